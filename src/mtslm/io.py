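"""Configuration, CSV input, and the end-to-end analysis pipeline.

The pipeline reproduces the standard workflow for this model class:
optional stratified train/test split, exhaustive AIC knot search on the
training data, Newton-Raphson fit of the selected specification, Wald
interval table, piecewise interpretation, comparison with plain binary
logistic regression, and classification metrics on the held-out split.
All artifacts are written as diff-able text (YAML spec, JSON fit, CSV
tables) plus diagnostic plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import SplineSpec, build_design_matrix
from .errors import DataError, MTSLMError
from .evaluation import classification_metrics, compare_models, train_test_split, vif
from .fit import inverse_logit, newton_raphson_fit
from .inference import interval_table
from .interpretation import piecewise_effects
from .knots import search_knots
from .simulate import empirical_logit_groups

__all__ = ["RunConfig", "read_dataset", "run_pipeline", "PipelineResult"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated settings for one pipeline run."""

    data: str | Path
    response: str
    predictors: list[str] | None = None
    degree: int = 1
    max_knots: int = 4
    strategy: str = "quantile"
    level: float = 0.95
    split: float = 0.8
    cutoff: float = 0.5
    seed: int = 0
    no_split: bool = False
    response_mapping: dict | None = None
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise MTSLMError(f"degree must be >= 1, got {self.degree}")
        if self.max_knots < 1:
            raise MTSLMError(f"max_knots must be >= 1, got {self.max_knots}")
        if not 0 < self.level < 1:
            raise MTSLMError(f"level must lie in (0,1), got {self.level}")
        if not 0 < self.split < 1:
            raise MTSLMError(f"split must lie in (0,1), got {self.split}")
        if not 0 <= self.cutoff <= 1:
            raise MTSLMError(f"cutoff must lie in [0,1], got {self.cutoff}")
        if self.strategy not in ("quantile", "uniform"):
            raise MTSLMError(f"unknown strategy {self.strategy!r}")


def read_dataset(path, config: RunConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a header-ed CSV into (predictor table, 0/1 response vector).

    The response column is coerced to {0,1}; non-numeric codings need an
    explicit ``response_mapping`` in the config.  All other configured
    columns must be numeric with no missing values.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"data file not found: {path}")
    df = pd.read_csv(path)
    if df.empty:
        raise DataError(f"data file is empty: {path}")
    if config.response not in df.columns:
        raise DataError(f"response column {config.response!r} not in {path.name}")
    predictors = config.predictors or [c for c in df.columns if c != config.response]
    missing = [c for c in predictors if c not in df.columns]
    if missing:
        raise DataError(f"predictor columns not found: {missing}")

    yraw = df[config.response]
    if config.response_mapping:
        unmapped = set(yraw.unique()) - set(config.response_mapping)
        if unmapped:
            raise DataError(f"response values without a mapping: {sorted(unmapped)}")
        yraw = yraw.map(config.response_mapping)
    y = pd.to_numeric(yraw, errors="coerce").to_numpy(dtype=float)
    if np.isnan(y).any() or not np.isin(y, (0.0, 1.0)).all():
        raise DataError(
            "response is not coded 0/1; supply response_mapping for other codings"
        )
    X = df[predictors].apply(pd.to_numeric, errors="coerce")
    if X.isna().any().any():
        col = X.columns[X.isna().any()][0]
        row = int(X[X[col].isna()].index[0])
        raise DataError(f"missing/non-numeric value in column {col!r} at row {row}")
    log.info("read %d rows, %d predictors, %d/%d class balance",
             len(df), len(predictors), int(y.sum()), int((1 - y).sum()))
    return X, y


@dataclass
class PipelineResult:
    """Everything the end-to-end pipeline produced."""

    config: RunConfig
    spec: SplineSpec
    search: object
    fit: object
    plain_fit: object
    intervals: object
    comparison: pd.DataFrame
    metrics: pd.DataFrame
    effects: list = field(default_factory=list)
    vif: pd.Series | None = None


def _plain_design(X: pd.DataFrame):
    return np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])


def run_pipeline(config: RunConfig, data: pd.DataFrame | None = None,
                 y: np.ndarray | None = None) -> PipelineResult:
    """Split, search knots, fit, infer, interpret, compare, score.

    ``data``/``y`` may be passed directly (e.g. a synthetic dataset);
    otherwise they are read from ``config.data``.  With ``no_split`` the
    model is selected, fitted and scored on the full data (the alternative
    full-data workflow); otherwise selection and fitting use the training
    split and classification metrics the held-out test split.
    """
    if data is None or y is None:
        data, y = read_dataset(config.data, config)

    vif_table = vif(data) if data.shape[1] >= 2 else None

    if config.no_split:
        X_train = X_test = data
        y_train = y_test = y
    else:
        X_train, X_test, y_train, y_test = train_test_split(
            data, y, fraction=config.split, seed=config.seed, stratified=True
        )

    search = search_knots(
        X_train, y_train, degree=config.degree, max_knots=config.max_knots,
        strategy=config.strategy,
    )
    spec = search.best
    fit = search.best_fit
    intervals = interval_table(fit, level=config.level)

    plain_fit = newton_raphson_fit(_plain_design(X_train), y_train)
    comparison = compare_models(fit, plain_fit)

    def score(f, X):
        return inverse_logit(build_design_matrix(X, spec).values @ f.beta)

    probs_spline = score(fit, X_test)
    probs_plain = inverse_logit(_plain_design(X_test) @ plain_fit.beta)
    rep_spline = classification_metrics(probs_spline, y_test, cutoff=config.cutoff)
    rep_plain = classification_metrics(probs_plain, y_test, cutoff=config.cutoff)
    metrics = pd.DataFrame(
        [
            {"model": "binary_logistic", **rep_plain.to_row()},
            {"model": "mtslm", **rep_spline.to_row()},
        ]
    )

    effects = []
    if config.degree == 1:
        effects = [piecewise_effects(fit, spec, name) for name in spec.predictor_names]

    result = PipelineResult(
        config=config, spec=spec, search=search, fit=fit, plain_fit=plain_fit,
        intervals=intervals, comparison=comparison, metrics=metrics,
        effects=effects, vif=vif_table,
    )
    if config.outdir is not None:
        _write_artifacts(result, data, y)
    return result


def _write_artifacts(result: PipelineResult, data: pd.DataFrame, y: np.ndarray) -> None:
    out = Path(result.config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.spec.to_yaml(out / "spec.yaml")
    result.fit.to_json(out / "fit.json")
    result.plain_fit.to_json(out / "fit_plain.json")
    result.search.to_csv(out / "knot_search.csv")
    result.intervals.to_csv(out / "intervals.csv")
    result.comparison.to_csv(out / "comparison.csv", index=False)
    result.metrics.to_csv(out / "metrics.csv", index=False)
    if result.vif is not None:
        result.vif.to_csv(out / "vif.csv")
    if result.effects:
        rows = [
            {
                "predictor": eff.predictor,
                "lower": seg.lower,
                "upper": seg.upper,
                "effective_slope": seg.effective_slope,
                "offset": seg.offset,
                "odds_ratio_per_unit": seg.odds_ratio_per_unit,
            }
            for eff in result.effects
            for seg in eff.segments
        ]
        pd.DataFrame(rows).to_csv(out / "piecewise_effects.csv", index=False)
    try:
        from .plots import plot_coefficient_intervals, plot_empirical_logits

        plot_coefficient_intervals(result.intervals, out / "intervals.png")
        plot_empirical_logits(data, y, out / "empirical_logits.png")
    except Exception as exc:  # plotting must never sink the analysis
        log.warning("plotting failed: %s", exc)


def empirical_logit_report(data: pd.DataFrame, y, n_groups: int = 15) -> dict[str, pd.DataFrame]:
    """Binned empirical logits for every predictor (diagnostic tables)."""
    return {c: empirical_logit_groups(data[c], y, n_groups) for c in data.columns}
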