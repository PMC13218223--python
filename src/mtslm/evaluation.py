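"""Model comparison and classification diagnostics.

The spline logistic model is judged against plain binary logistic
regression on two axes: likelihood-based fit (deviance and AIC on the same
data) and out-of-sample classification at a probability cutoff (confusion
matrix, accuracy, sensitivity, specificity, F1, and rank-based AUC).  A VIF
screen flags multicollinearity among the raw predictors before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.model_selection import train_test_split as _sk_split

from .errors import DataError, MTSLMError
from .fit import FitResult

__all__ = [
    "ClassificationReport",
    "train_test_split",
    "classification_metrics",
    "vif",
    "compare_models",
]


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion counts at a cutoff plus threshold-free AUC."""

    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float

    def to_row(self) -> dict:
        return {
            "AUC": self.auc,
            "Accuracy": self.accuracy,
            "Sensitivity": self.sensitivity,
            "Specificity": self.specificity,
            "F1": self.f1,
        }


def train_test_split(data: pd.DataFrame, y, fraction: float = 0.8, seed: int = 0,
                     stratified: bool = True):
    """Reproducible train/test partition; stratified by response by default.

    Returns ``(data_train, data_test, y_train, y_test)`` with
    ``len(train) = round(fraction * n)``; no overlap, full cover.
    """
    if not 0.0 < fraction < 1.0:
        raise MTSLMError(f"fraction must lie in (0,1), got {fraction}")
    y = np.asarray(y)
    if stratified:
        counts = pd.Series(y).value_counts()
        if (counts < 2).any():
            raise DataError(
                f"cannot stratify: smallest response class has {counts.min()} row(s)"
            )
    return _sk_split(
        data, y, train_size=fraction, random_state=seed,
        stratify=y if stratified else None, shuffle=True,
    )


def _midrank_auc(probs: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC with midrank tie handling."""
    n1 = int(y.sum())
    n0 = y.size - n1
    ranks = rankdata(probs)  # midranks
    return (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def classification_metrics(probs, y, cutoff: float = 0.5) -> ClassificationReport:
    """Score predicted probabilities against a 0/1 response.

    Predictions use ``prob >= cutoff -> class 1`` (a tie at the cutoff maps
    to 1).  AUC is the rank-based Mann-Whitney statistic with midranks for
    ties, i.e. the probability a random positive outscores a random
    negative, ties counting one half.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=float)
    if probs.shape != y.shape:
        raise DataError("probs and y must have the same length")
    if np.any((probs < 0) | (probs > 1)):
        raise DataError("probabilities must lie in [0,1]")
    if not np.isin(y, (0.0, 1.0)).all():
        raise DataError("response must be coded 0/1")
    if y.min() == y.max():
        raise DataError("AUC undefined: response contains a single class")

    pred = (probs >= cutoff).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    total = tp + fp + tn + fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn)
    return ClassificationReport(
        cutoff=cutoff,
        tp=tp, fp=fp, tn=tn, fn=fn,
        auc=_midrank_auc(probs, y),
        accuracy=(tp + tn) / total,
        sensitivity=recall,
        specificity=tn / (tn + fp),
        f1=(2 * precision * recall / (precision + recall)) if precision + recall else 0.0,
    )


def vif(predictors: pd.DataFrame) -> pd.Series:
    """Variance inflation factors 1/(1 - R2_j) of the raw predictors.

    Each predictor is regressed (OLS with intercept) on all the others;
    values are >= 1 by construction, with np.inf flagging perfect
    collinearity.  Values above 10 conventionally indicate problematic
    multicollinearity.
    """
    if predictors.shape[1] < 2:
        raise DataError("VIF needs at least two predictors")
    out = {}
    for col in predictors.columns:
        xj = predictors[col].to_numpy(dtype=float)
        if np.ptp(xj) == 0:
            raise DataError(f"predictor {col!r} is constant")
        others = sm.add_constant(predictors.drop(columns=[col]).to_numpy(dtype=float))
        r2 = sm.OLS(xj, others).fit().rsquared
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def compare_models(spline_fit: FitResult, plain_fit: FitResult) -> pd.DataFrame:
    """Deviance/AIC comparison table; the winner is the lower-AIC model."""
    if spline_fit.n_obs != plain_fit.n_obs:
        raise DataError(
            f"fits are on different data: n={spline_fit.n_obs} vs {plain_fit.n_obs}"
        )
    table = pd.DataFrame(
        {
            "model": ["binary_logistic", "mtslm"],
            "deviance": [plain_fit.deviance, spline_fit.deviance],
            "aic": [plain_fit.aic, spline_fit.aic],
            "n_params": [plain_fit.n_params, spline_fit.n_params],
        }
    )
    if np.isclose(spline_fit.aic, plain_fit.aic, rtol=0, atol=1e-10):
        winner = None
    else:
        winner = "mtslm" if spline_fit.aic < plain_fit.aic else "binary_logistic"
    table.attrs["winner"] = winner
    return table
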