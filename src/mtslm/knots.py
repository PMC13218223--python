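"""AIC-driven knot selection by exhaustive enumeration of knot counts.

For ``p`` predictors and a per-predictor count budget of ``max_knots``, the
search fits every combination in ``{1..max_knots}^p`` (an odometer with the
last predictor ticking fastest: 64 candidates for p=3, 256 for p=4 at
``max_knots=4``), places the knots for each count with a deterministic rule,
and keeps the specification minimizing AIC = deviance + 2q.  Candidates
whose fit fails (rank deficiency, separation, non-convergence) are recorded
but excluded from the minimum.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import SplineSpec, build_design_matrix
from .errors import DataError, MTSLMError, NumericalError
from .fit import FitResult, newton_raphson_fit

__all__ = ["KnotSearchResult", "candidate_knots", "search_knots"]

log = logging.getLogger(__name__)


@dataclass
class KnotSearchResult:
    """Outcome of the exhaustive knot-count search.

    ``records`` holds one row per enumerated count combination, in
    enumeration order: the counts, the placed knot locations, the AIC (NaN
    when the candidate failed) and a convergence flag.  ``best``/``best_fit``
    are the minimum-AIC specification and its fit.
    """

    records: pd.DataFrame
    best: SplineSpec
    best_fit: FitResult
    search_space_size: int

    def to_csv(self, path) -> None:
        out = self.records.copy()
        out["combination"] = out["combination"].map(lambda t: ",".join(map(str, t)))
        out.drop(columns=["knots"]).to_csv(path, index=False)


def candidate_knots(x, count: int, strategy: str = "quantile") -> np.ndarray:
    """Place ``count`` interior knots for one predictor.

    ``quantile`` puts knots at the ``i/(count+1)`` empirical quantiles,
    ``uniform`` at equally spaced interior points of the observed range;
    both keep knots strictly inside the data so every truncated column has
    support.
    """
    x = np.asarray(x, dtype=float)
    if count < 1:
        raise MTSLMError(f"knot count must be >= 1, got {count}")
    if np.unique(x).size < count + 2:
        raise DataError(
            f"predictor has only {np.unique(x).size} distinct values; "
            f"cannot place {count} interior knots"
        )
    probs = np.arange(1, count + 1) / (count + 1)
    if strategy == "quantile":
        knots = np.quantile(x, probs)
    elif strategy == "uniform":
        lo, hi = x.min(), x.max()
        knots = lo + probs * (hi - lo)
    else:
        raise MTSLMError(f"unknown knot strategy {strategy!r}")
    if not np.all(np.diff(knots) > 0) or knots[0] <= x.min() or knots[-1] >= x.max():
        raise DataError(
            "degenerate predictor: placed knots are not strictly interior "
            "and increasing (too many ties?)"
        )
    return knots


def search_knots(
    data: pd.DataFrame,
    y,
    degree: int = 1,
    max_knots: int = 4,
    strategy: str = "quantile",
    min_knots: int = 1,
    predictor_names=None,
) -> KnotSearchResult:
    """Fit every knot-count combination and select the AIC minimizer.

    Ties on AIC break toward fewer total knots, then enumeration order.
    ``min_knots=0`` admits knot-free predictors (plain linear terms).
    """
    if max_knots < 1:
        raise MTSLMError(f"max_knots must be >= 1, got {max_knots}")
    if not isinstance(data, pd.DataFrame):
        data = pd.DataFrame(np.asarray(data, dtype=float))
        data.columns = [f"x{j + 1}" for j in range(data.shape[1])]
    names = list(predictor_names) if predictor_names is not None else list(data.columns)
    p = len(names)
    y = np.asarray(y, dtype=float)

    # knot placement depends only on the predictor and the count: precompute
    placed: dict[tuple[str, int], np.ndarray] = {}
    for name in names:
        for count in range(max(min_knots, 1), max_knots + 1):
            placed[(name, count)] = candidate_knots(data[name], count, strategy)

    counts_range = range(min_knots, max_knots + 1)
    rows = []
    best = None  # (aic, total_knots, order_index, spec, fit)
    combos = list(itertools.product(counts_range, repeat=p))
    for idx, combo in enumerate(combos):
        knots = {
            name: tuple(placed[(name, c)]) if c > 0 else ()
            for name, c in zip(names, combo)
        }
        spec = SplineSpec(degree=degree, knots=knots, predictor_names=tuple(names))
        aic, conv, fit = np.nan, False, None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                design = build_design_matrix(data, spec)
                fit = newton_raphson_fit(design, y)
            conv = fit.converged
            if conv:
                aic = fit.aic
        except NumericalError as exc:
            log.warning("combination %s failed: %s", combo, exc)
        rows.append({"no": idx + 1, "combination": combo, "knots": knots, "aic": aic,
                     "converged": conv})
        log.debug("knot search %d/%d: %s -> AIC %.4f", idx + 1, len(combos), combo, aic)
        if conv:
            key = (aic, sum(combo), idx)
            if best is None or key < best[0]:
                best = (key, spec, fit)

    if best is None:
        raise NumericalError("no knot combination produced a converged fit")
    records = pd.DataFrame(rows)
    return KnotSearchResult(
        records=records,
        best=best[1],
        best_fit=best[2],
        search_space_size=len(combos),
    )
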