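"""Bernoulli maximum likelihood for the spline logistic model.

The response is modelled as :math:`Y_i \\sim \\mathrm{Bernoulli}(\\pi_i)`
with :math:`\\mathrm{logit}(\\pi_i) = X_i'\\beta` on the expanded
truncated-power design.  The log-likelihood

.. math:: L(\\beta) = \\sum_i \\bigl[y_i X_i'\\beta - \\log(1 + e^{X_i'\\beta})\\bigr]

is globally concave; its score is :math:`X'(y - \\pi)` and Hessian
:math:`-X'WX` with :math:`W = \\mathrm{diag}[\\pi_i(1-\\pi_i)]`.  The MLE is
found by Newton-Raphson with step-halving, and the asymptotic covariance is
the inverse Fisher information :math:`(X'WX)^{-1}` at the optimum.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.special import expit

from .basis import DesignMatrix
from .errors import DataError, SeparationError, SingularInformationError

__all__ = [
    "FitResult",
    "inverse_logit",
    "log_likelihood",
    "score_and_hessian",
    "newton_raphson_fit",
    "fit_statistics",
]

#: |beta_j| beyond this is treated as evidence of separation (logistic
#: coefficients of genuine data on any sane scale stay far below it).
SEPARATION_BOUND = 1e3


@dataclass
class FitResult:
    """Converged (or diagnosed) maximum-likelihood fit.

    ``aic = deviance + 2 * n_params`` with ``deviance = -2 * log_likelihood``
    holds by construction and is the quantity minimized during knot search.
    """

    beta: np.ndarray
    covariance: np.ndarray
    log_likelihood: float
    n_params: int
    iterations: int
    converged: bool
    n_obs: int
    param_names: tuple[str, ...] = ()
    trajectory: list[float] = field(default_factory=list)

    @property
    def deviance(self) -> float:
        return -2.0 * self.log_likelihood

    @property
    def aic(self) -> float:
        return self.deviance + 2.0 * self.n_params

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.tolist(),
            "covariance": self.covariance.tolist(),
            "log_likelihood": self.log_likelihood,
            "deviance": self.deviance,
            "aic": self.aic,
            "n_params": self.n_params,
            "iterations": self.iterations,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "param_names": list(self.param_names),
            "trajectory": list(self.trajectory),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            beta=np.asarray(d["beta"], dtype=float),
            covariance=np.asarray(d["covariance"], dtype=float),
            log_likelihood=float(d["log_likelihood"]),
            n_params=int(d["n_params"]),
            iterations=int(d["iterations"]),
            converged=bool(d["converged"]),
            n_obs=int(d["n_obs"]),
            param_names=tuple(d.get("param_names", ())),
            trajectory=list(d.get("trajectory", ())),
        )

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def inverse_logit(eta):
    """Logistic function exp(eta)/(1+exp(eta)), overflow-safe.

    Saturates smoothly and is clamped to the open interval (0,1): extreme
    linear predictors return the closest representable probability rather
    than exactly 0 or 1.
    """
    out = expit(np.asarray(eta, dtype=float))
    out = np.clip(out, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
    return out if out.ndim else float(out)


def _design_values(design) -> np.ndarray:
    return design.values if isinstance(design, DesignMatrix) else np.asarray(design, float)


def _check_response(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        bad = y[~np.isin(y, (0.0, 1.0))][:3]
        raise DataError(f"response must be coded 0/1; offending values: {bad.tolist()}")
    return y


def log_likelihood(beta, design, y) -> float:
    """Bernoulli log-likelihood at ``beta``; overflow-safe in the linear predictor."""
    X = _design_values(design)
    y = _check_response(y)
    eta = X @ np.asarray(beta, dtype=float)
    # log(1 + e^eta) computed as logaddexp(0, eta): exact for |eta| ~ 1e3
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def score_and_hessian(beta, design, y):
    """Score vector X'(y - pi) and Hessian -X'WX at ``beta``."""
    X = _design_values(design)
    y = _check_response(y)
    pi = expit(X @ np.asarray(beta, dtype=float))
    w = pi * (1.0 - pi)
    score = X.T @ (y - pi)
    hessian = -(X.T * w) @ X
    return score, hessian


def newton_raphson_fit(
    design,
    y,
    init=None,
    tol: float = 1e-8,
    max_iter: int = 100,
    separation_bound: float = SEPARATION_BOUND,
) -> FitResult:
    """Maximize the Bernoulli log-likelihood by damped Newton-Raphson.

    Iterates ``beta <- beta + (X'WX)^{-1} X'(y - pi)`` from ``init``
    (default: the zero vector, i.e. pi = 1/2 everywhere), halving the step
    up to 10 times whenever a full step would decrease the log-likelihood,
    until the max-norm of the update falls below ``tol``.

    Raises
    ------
    SingularInformationError
        If the design is rank-deficient (e.g. a knot outside the data range
        produced an all-zero or collinear column).
    SeparationError
        If the iterates diverge (``max |beta| > separation_bound`` or fitted
        probabilities pinned at 0/1), the signature of complete separation.
    """
    X = _design_values(design)
    y = _check_response(y)
    n, q = X.shape
    if y.shape[0] != n:
        raise DataError(f"response length {y.shape[0]} != design rows {n}")
    if n <= q:
        warnings.warn(f"n={n} <= q={q}: fit is ill-determined", stacklevel=2)
    if np.linalg.matrix_rank(X) < q:
        raise SingularInformationError(
            f"design matrix is rank-deficient (rank < q={q}); "
            "check for knots outside the data range or duplicated columns"
        )

    beta = np.zeros(q) if init is None else np.asarray(init, dtype=float).copy()
    ll = log_likelihood(beta, X, y)
    trajectory = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pi = expit(X @ beta)
        w = pi * (1.0 - pi)
        info = (X.T * w) @ X  # = -Hessian = Fisher information
        score = X.T @ (y - pi)
        try:
            step = linalg.solve(info, score, assume_a="pos")
        except linalg.LinAlgError as exc:
            if np.any(pi < 1e-10) or np.any(pi > 1 - 1e-10):
                raise SeparationError(
                    "fitted probabilities pinned at 0/1: data are separated; "
                    "try fewer knots"
                ) from exc
            raise SingularInformationError(
                "Fisher information singular during iteration"
            ) from exc

        # step-halving: never accept a likelihood decrease
        scale = 1.0
        for _ in range(10):
            candidate = beta + scale * step
            ll_new = log_likelihood(candidate, X, y)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = candidate
        ll = ll_new
        trajectory.append(ll)

        if np.max(np.abs(beta)) > separation_bound:
            raise SeparationError(
                f"coefficients diverged beyond {separation_bound:g}: data are "
                "(quasi-)separated; try fewer knots"
            )
        if np.max(np.abs(scale * step)) < tol:
            converged = True
            break

    if not converged:
        pi = expit(X @ beta)
        if np.any(pi < 1e-10) or np.any(pi > 1 - 1e-10):
            raise SeparationError(
                "no convergence and fitted probabilities pinned at 0/1: "
                "data are separated; try fewer knots"
            )

    pi = expit(X @ beta)
    w = pi * (1.0 - pi)
    info = (X.T * w) @ X
    try:
        covariance = linalg.inv(info)
    except linalg.LinAlgError as exc:
        raise SingularInformationError("Fisher information singular at optimum") from exc

    names = design.column_layout if isinstance(design, DesignMatrix) else ()
    return FitResult(
        beta=beta,
        covariance=covariance,
        log_likelihood=ll,
        n_params=q,
        iterations=it,
        converged=converged,
        n_obs=n,
        param_names=tuple(names),
        trajectory=trajectory,
    )


def fit_statistics(fit: FitResult) -> tuple[float, float]:
    """Return ``(deviance, aic)`` of a fit: -2L and -2L + 2q."""
    return fit.deviance, fit.aic
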