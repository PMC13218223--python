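"""Piecewise-linear readout of a fitted degree-1 spline logistic model.

For degree 1 the logit contribution of predictor ``x`` is

    f(x) = b1 * x + sum_u c_u * (x - K_u)+

which is continuous piecewise-linear: on the segment between consecutive
knots ``[K_u, K_{u+1})`` the effective slope is the cumulative sum
``b1 + c_1 + ... + c_u`` and the per-unit odds ratio is ``exp(slope)``.
Segment intercepts are reconstructed from continuity at each knot
(offset_u = offset_{u-1} - c_u * K_u), so evaluating the segment formulas
reproduces the truncated-power expression exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .basis import SplineSpec
from .errors import MTSLMError
from .fit import FitResult

__all__ = ["Segment", "PiecewiseEffect", "piecewise_effects", "odds_ratio"]


@dataclass(frozen=True)
class Segment:
    """One sub-interval of a predictor's piecewise-linear logit effect."""

    lower: float  # inclusive; -inf on the first segment
    upper: float  # exclusive; +inf on the last
    effective_slope: float
    offset: float
    odds_ratio_per_unit: float

    def evaluate(self, x: float) -> float:
        return self.effective_slope * x + self.offset


@dataclass(frozen=True)
class PiecewiseEffect:
    """All segments of one predictor, holding the others fixed."""

    predictor: str
    breakpoints: tuple[float, ...]
    segments: tuple[Segment, ...]

    def evaluate(self, x) -> np.ndarray:
        """Evaluate the predictor's logit contribution via the segment formulas."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        idx = np.searchsorted(self.breakpoints, x, side="right")
        return np.array([self.segments[i].evaluate(v) for i, v in zip(idx, x)])


def _coefficient_slice(spec: SplineSpec, predictor: str) -> tuple[int, int]:
    """(base-slope index, first-knot-coefficient index) for a predictor."""
    offset = 1
    for name in spec.predictor_names:
        if name == predictor:
            return offset, offset + spec.degree
        offset += spec.degree + len(spec.knots[name])
    raise MTSLMError(f"unknown predictor {predictor!r}")


def piecewise_effects(fit: FitResult, spec: SplineSpec, predictor: str) -> PiecewiseEffect:
    """Segment slopes, offsets, and per-unit odds ratios for one predictor.

    Requires ``spec.degree == 1`` (for higher degrees the effect is not
    piecewise-linear and a single slope per segment does not exist).
    """
    if spec.degree != 1:
        raise MTSLMError(
            f"piecewise interpretation requires degree 1, got {spec.degree}"
        )
    if len(fit.beta) != spec.n_params:
        raise MTSLMError(
            f"fit has {len(fit.beta)} coefficients but spec implies {spec.n_params}"
        )
    base_idx, knot_idx = _coefficient_slice(spec, predictor)
    knots = np.asarray(spec.knots[predictor], dtype=float)
    base = float(fit.beta[base_idx])
    coefs = np.asarray(fit.beta[knot_idx : knot_idx + knots.size], dtype=float)

    slopes = base + np.concatenate([[0.0], np.cumsum(coefs)])
    # continuity at K_u: offset_u = offset_{u-1} - c_u * K_u
    offsets = np.concatenate([[0.0], np.cumsum(-coefs * knots)])
    bounds = np.concatenate([[-np.inf], knots, [np.inf]])
    segments = tuple(
        Segment(
            lower=float(bounds[u]),
            upper=float(bounds[u + 1]),
            effective_slope=float(slopes[u]),
            offset=float(offsets[u]),
            odds_ratio_per_unit=odds_ratio(float(slopes[u])),
        )
        for u in range(slopes.size)
    )
    return PiecewiseEffect(
        predictor=predictor, breakpoints=tuple(knots.tolist()), segments=segments
    )


def odds_ratio(slope: float) -> float:
    """Multiplicative change in the odds per unit increase: exp(slope)."""
    if not math.isfinite(slope):
        raise MTSLMError(f"slope must be finite, got {slope}")
    return math.exp(slope)
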