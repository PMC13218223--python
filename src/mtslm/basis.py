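"""Truncated power spline basis and design-matrix construction.

A degree-``m`` truncated power basis for predictor :math:`x_j` with knots
:math:`K_{j1} < \\dots < K_{jr_j}` consists of the monomials
:math:`x_j, x_j^2, \\dots, x_j^m` followed by the truncated terms
:math:`(x_j - K_{ju})_+^m`, where :math:`(t)_+ = \\max(t, 0)`.  Stacking the
bases of all ``p`` predictors behind a leading intercept column gives the
full design matrix with

.. math:: q = 1 + \\sum_{j=1}^p (m + r_j)

columns.  The resulting fit is a continuous piecewise polynomial in every
predictor: the local polynomial coefficients are allowed to change at each
knot while the function value matches across it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, SpecError

__all__ = [
    "SplineSpec",
    "DesignMatrix",
    "truncated_power_term",
    "build_design_matrix",
]


@dataclass(frozen=True)
class SplineSpec:
    """Degree and per-predictor knot locations defining an MTSLM basis.

    Parameters
    ----------
    degree
        Spline degree ``m >= 1``.  Degree 1 gives piecewise-linear logits,
        the configuration used for interpretable threshold effects.
    knots
        Mapping from predictor name to a strictly increasing sequence of
        knot locations, on the raw scale of the predictor.  Knot counts may
        differ across predictors.
    predictor_names
        Column order of the predictors; defaults to the key order of
        ``knots``.
    """

    degree: int
    knots: dict[str, tuple[float, ...]]
    predictor_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if int(self.degree) != self.degree or self.degree < 1:
            raise SpecError(f"degree must be a positive integer, got {self.degree!r}")
        object.__setattr__(self, "degree", int(self.degree))
        names = tuple(self.predictor_names) or tuple(self.knots)
        if set(names) != set(self.knots):
            raise SpecError("predictor_names must match the keys of knots")
        object.__setattr__(self, "predictor_names", names)
        clean: dict[str, tuple[float, ...]] = {}
        for name in names:
            kv = np.asarray(self.knots[name], dtype=float)
            if kv.ndim != 1:
                raise SpecError(f"{name}: knot vector must be a 1-d sequence")
            if not np.all(np.isfinite(kv)):
                raise SpecError(f"{name}: knots must be finite")
            if not np.all(np.diff(kv) > 0):
                raise SpecError(f"{name}: knots must be strictly increasing, got {kv.tolist()}")
            clean[name] = tuple(kv.tolist())
        object.__setattr__(self, "knots", clean)

    @property
    def p(self) -> int:
        """Number of predictors."""
        return len(self.predictor_names)

    @property
    def knot_counts(self) -> tuple[int, ...]:
        return tuple(len(self.knots[name]) for name in self.predictor_names)

    @property
    def n_params(self) -> int:
        """Total parameter count ``q = 1 + sum_j (m + r_j)``."""
        return 1 + sum(self.degree + r for r in self.knot_counts)

    def column_labels(self) -> list[str]:
        """Design-matrix column labels in construction order."""
        labels = ["intercept"]
        for name in self.predictor_names:
            for k in range(1, self.degree + 1):
                labels.append(name if k == 1 else f"{name}^{k}")
            for knot in self.knots[name]:
                suffix = "" if self.degree == 1 else f"^{self.degree}"
                labels.append(f"({name}-{knot:g})+{suffix}")
        return labels

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "knots": {name: list(self.knots[name]) for name in self.predictor_names},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        return cls(degree=d["degree"], knots={k: tuple(v) for k, v in d["knots"].items()})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SplineSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class DesignMatrix:
    """Expanded n x q design matrix with its column layout."""

    values: np.ndarray
    column_layout: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def q(self) -> int:
        return self.values.shape[1]


def truncated_power_term(x, knot: float, degree: int):
    """Evaluate the truncated power function ``(x - knot)_+^degree``.

    Returns ``(x - knot)**degree`` where ``x > knot`` and exactly 0
    elsewhere (the boundary ``x == knot`` maps to 0).  Vectorized over
    ``x``; continuous in ``x`` at the knot for any ``degree >= 1``.
    """
    if int(degree) != degree or degree < 1:
        raise SpecError(f"degree must be a positive integer, got {degree!r}")
    x = np.asarray(x, dtype=float)
    if not (np.all(np.isfinite(x)) and np.isfinite(knot)):
        raise SpecError("truncated_power_term requires finite x and knot")
    out = np.where(x > knot, np.power(np.maximum(x - knot, 0.0), degree), 0.0)
    return out if out.ndim else float(out)


def build_design_matrix(raw, spec: SplineSpec) -> DesignMatrix:
    """Expand raw predictors into the truncated-power design matrix.

    Parameters
    ----------
    raw
        ``pandas.DataFrame`` containing (at least) the predictor columns
        named in ``spec``, or an n x p array whose columns follow
        ``spec.predictor_names`` order.
    spec
        The basis specification.

    Returns
    -------
    DesignMatrix
        First column all ones, then for each predictor its ``m`` monomial
        columns followed by its truncated columns, in knot order.
    """
    if isinstance(raw, pd.DataFrame):
        missing = [c for c in spec.predictor_names if c not in raw.columns]
        if missing:
            raise DataError(f"missing predictor columns: {missing}")
        X = raw.loc[:, list(spec.predictor_names)].to_numpy(dtype=float)
    else:
        X = np.asarray(raw, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != spec.p:
            raise DataError(
                f"raw has {X.shape[1]} columns but spec defines {spec.p} predictors"
            )
    bad = np.argwhere(~np.isfinite(X))
    if bad.size:
        i, j = bad[0]
        raise DataError(
            f"non-finite value in predictor {spec.predictor_names[j]!r} at row {i}"
        )

    n = X.shape[0]
    cols = [np.ones(n)]
    for j, name in enumerate(spec.predictor_names):
        xj = X[:, j]
        for k in range(1, spec.degree + 1):
            cols.append(xj**k)
        for knot in spec.knots[name]:
            cols.append(truncated_power_term(xj, knot, spec.degree))
    return DesignMatrix(
        values=np.column_stack(cols), column_layout=tuple(spec.column_labels())
    )
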