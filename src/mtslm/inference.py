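"""Pivotal-quantity (Wald) confidence intervals for the spline logistic MLE.

By asymptotic normality of the MLE, :math:`Z_j = (\\hat\\beta_j - \\beta_j)
/ \\widehat{SE}(\\hat\\beta_j)` is an (asymptotically) standard-normal pivot,
with :math:`\\widehat{SE}` the square root of the corresponding diagonal
entry of the inverse Fisher information.  Among all intervals
:math:`[\\hat\\beta_j - d\\,SE, \\hat\\beta_j - c\\,SE]` with coverage
:math:`\\Phi(d) - \\Phi(c) = 1 - \\alpha`, the shortest one is the symmetric
choice :math:`c = -d = -z_{\\alpha/2}` (a Lagrange-multiplier argument on
the interval length; :func:`shortest_interval_check` verifies this
numerically).  A parameter is flagged significant at level :math:`1-\\alpha`
when its interval excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

from .errors import MTSLMError, NumericalError
from .fit import FitResult

__all__ = [
    "IntervalTable",
    "standard_errors",
    "wald_interval",
    "interval_table",
    "shortest_interval_check",
]


@dataclass(frozen=True)
class IntervalTable:
    """Per-parameter Wald intervals at confidence level ``level``.

    ``rows`` has columns parameter / estimate / se / lower / upper /
    significant; every interval is symmetric about its estimate with
    half-width ``z_half_alpha * se``.
    """

    level: float
    z_half_alpha: float
    rows: pd.DataFrame

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def standard_errors(fit: FitResult) -> np.ndarray:
    """Asymptotic standard errors: sqrt of the diagonal of (X'WX)^-1."""
    diag = np.diag(fit.covariance)
    if np.any(diag <= 0):
        raise NumericalError(
            "non-positive diagonal in the inverse Fisher information; "
            "the fit is numerically degenerate"
        )
    return np.sqrt(diag)


def wald_interval(estimate: float, se: float, level: float = 0.95):
    """Symmetric normal-theory interval ``estimate -+ z_{alpha/2} * se``."""
    if not 0.0 < level < 1.0:
        raise MTSLMError(f"confidence level must lie in (0,1), got {level}")
    if se <= 0:
        raise MTSLMError(f"standard error must be positive, got {se}")
    z = norm.ppf(0.5 + level / 2.0)
    return estimate - z * se, estimate + z * se


def interval_table(fit: FitResult, level: float = 0.95, bonferroni: bool = False) -> IntervalTable:
    """Wald interval and significance flag for every model parameter.

    ``significant`` is strict exclusion of zero (an interval touching zero
    counts as non-significant).  ``bonferroni=True`` divides alpha by the
    parameter count before forming the intervals; the default reports the
    conventional unadjusted per-parameter intervals.
    """
    if not 0.0 < level < 1.0:
        raise MTSLMError(f"confidence level must lie in (0,1), got {level}")
    se = standard_errors(fit)
    eff_level = 1.0 - (1.0 - level) / fit.n_params if bonferroni else level
    z = norm.ppf(0.5 + eff_level / 2.0)
    lower = fit.beta - z * se
    upper = fit.beta + z * se
    names = fit.param_names or tuple(f"beta_{j}" for j in range(fit.n_params))
    rows = pd.DataFrame(
        {
            "parameter": list(names),
            "estimate": fit.beta,
            "se": se,
            "lower": lower,
            "upper": upper,
            "significant": (lower > 0) | (upper < 0),
        }
    )
    return IntervalTable(level=level, z_half_alpha=z, rows=rows)


def shortest_interval_check(level: float = 0.95, grid_tol: float = 1e-6):
    """Numerically minimize the pivot-interval length at fixed coverage.

    Solves ``min d - c  s.t.  Phi(d) - Phi(c) = 1 - alpha`` by
    parameterizing ``d = Phi^{-1}(Phi(c) + 1 - alpha)`` and minimizing over
    ``c``.  Returns the minimizer ``(c, d)``, which for the unimodal
    symmetric normal density satisfies ``c = -d`` to within ``grid_tol`` —
    i.e. the equal-tail Wald interval is also the shortest.
    """
    if not 0.0 < level < 1.0:
        raise MTSLMError(f"confidence level must lie in (0,1), got {level}")
    alpha = 1.0 - level

    def length(c: float) -> float:
        return norm.ppf(norm.cdf(c) + level) - c

    # c must satisfy Phi(c) < alpha; stay strictly inside for ppf stability
    upper_c = norm.ppf(alpha) - 1e-9
    res = optimize.minimize_scalar(
        length, bounds=(-12.0, upper_c), method="bounded",
        options={"xatol": min(grid_tol, 1e-9) / 10},
    )
    c = float(res.x)
    d = float(norm.ppf(norm.cdf(c) + level))
    return c, d
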