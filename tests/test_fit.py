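import numpy as np
import pytest
from scipy.special import logit

from mtslm import (
    DataError,
    SeparationError,
    SingularInformationError,
    build_design_matrix,
    fit_statistics,
    generate_dataset,
    inverse_logit,
    log_likelihood,
    newton_raphson_fit,
    sim_study_preset,
    score_and_hessian,
)


def test_inverse_logit_values():
    assert inverse_logit(0.0) == 0.5
    assert inverse_logit(np.log(3.0)) == pytest.approx(0.75)
    big = inverse_logit(1000.0)
    assert 1 - 1e-12 < big < 1.0
    assert inverse_logit(-1000.0) > 0.0


def test_log_likelihood_closed_forms():
    rng = np.random.default_rng(0)
    X = np.column_stack([np.ones(8), rng.normal(size=8)])
    y = rng.integers(0, 2, size=8).astype(float)
    assert log_likelihood(np.zeros(2), X, y) == pytest.approx(-8 * np.log(2))
    # single observation with X'beta = log 3 and y = 1: L = log pi = log 0.75
    assert log_likelihood([np.log(3)], np.ones((1, 1)), [1.0]) == pytest.approx(
        np.log(0.75)
    )


def test_log_likelihood_matches_bernoulli_product_oracle():
    """Direct product of Bernoulli pmfs, then log, on a random instance."""
    rng = np.random.default_rng(3)
    X = np.column_stack([np.ones(12), rng.normal(size=(12, 2))])
    beta = rng.normal(size=3)
    y = rng.integers(0, 2, size=12).astype(float)
    pi = 1 / (1 + np.exp(-(X @ beta)))
    oracle = np.log(np.prod(pi**y * (1 - pi) ** (1 - y)))
    assert log_likelihood(beta, X, y) == pytest.approx(oracle, rel=1e-12)


def test_log_likelihood_rejects_nonbinary_response():
    with pytest.raises(DataError):
        log_likelihood([0.0], np.ones((3, 1)), [0.0, 1.0, 2.0])


def test_score_and_hessian_match_finite_differences():
    rng = np.random.default_rng(7)
    X = np.column_stack([np.ones(30), rng.normal(size=(30, 2))])
    y = rng.integers(0, 2, size=30).astype(float)
    beta = rng.normal(scale=0.5, size=3)
    score, hess = score_and_hessian(beta, X, y)

    eps = 1e-6
    for j in range(3):
        e = np.zeros(3)
        e[j] = eps
        num = (log_likelihood(beta + e, X, y) - log_likelihood(beta - e, X, y)) / (2 * eps)
        assert score[j] == pytest.approx(num, rel=1e-5, abs=1e-7)
        num_h = (
            score_and_hessian(beta + e, X, y)[0] - score_and_hessian(beta - e, X, y)[0]
        ) / (2 * eps)
        np.testing.assert_allclose(hess[:, j], num_h, rtol=1e-5, atol=1e-6)

    np.testing.assert_allclose(hess, hess.T, atol=1e-12)
    assert np.all(np.linalg.eigvalsh(hess) <= 1e-10)  # negative semi-definite


def test_intercept_only_mle_is_logit_of_mean():
    y = np.array([1.0] * 7 + [0.0] * 13)
    fit = newton_raphson_fit(np.ones((20, 1)), y)
    assert fit.converged
    assert fit.beta[0] == pytest.approx(logit(7 / 20), abs=1e-8)
    # scalar information: SE = 1/sqrt(n p (1-p)) checked in inference tests


def test_converged_fit_beats_null_and_is_monotone():
    spec, beta = sim_study_preset()
    ds = generate_dataset(300, spec, beta, seed=2)
    dm = build_design_matrix(ds.predictors, spec)
    fit = newton_raphson_fit(dm, ds.y)
    assert fit.converged
    assert fit.log_likelihood >= log_likelihood(np.zeros(dm.q), dm, ds.y)
    assert fit.log_likelihood <= 0.0
    traj = np.asarray(fit.trajectory)
    assert np.all(np.diff(traj) >= -1e-10)
    # covariance symmetric positive definite at the optimum
    np.testing.assert_allclose(fit.covariance, fit.covariance.T, atol=1e-12)
    assert np.all(np.linalg.eigvalsh(fit.covariance) > 0)
    # score max-norm vanishes at the optimum
    score, _ = score_and_hessian(fit.beta, dm, ds.y)
    assert np.max(np.abs(score)) < 1e-6


def test_aic_bookkeeping_invariant():
    spec, beta = sim_study_preset()
    ds = generate_dataset(250, spec, beta, seed=4)
    dm = build_design_matrix(ds.predictors, spec)
    fit = newton_raphson_fit(dm, ds.y)
    deviance, aic = fit_statistics(fit)
    assert deviance == pytest.approx(-2 * fit.log_likelihood, abs=1e-12)
    assert aic - deviance == pytest.approx(2 * dm.q, abs=1e-12)


def test_rank_deficient_design_raises():
    rng = np.random.default_rng(0)
    x = rng.uniform(size=40)
    X = np.column_stack([np.ones(40), x, 2 * x])
    y = rng.integers(0, 2, size=40).astype(float)
    with pytest.raises(SingularInformationError):
        newton_raphson_fit(X, y)


def test_knot_outside_data_range_is_rejected():
    from mtslm import SplineSpec

    spec = SplineSpec(degree=1, knots={"x1": (2.0,)})  # all-zero truncated column
    rng = np.random.default_rng(1)
    X = rng.uniform(size=(50, 1))
    dm = build_design_matrix(X, spec)
    with pytest.raises(SingularInformationError):
        newton_raphson_fit(dm, rng.integers(0, 2, size=50).astype(float))


def test_separation_raises():
    x = np.linspace(-1, 1, 60)
    y = (x > 0).astype(float)  # perfectly separated
    X = np.column_stack([np.ones(60), x])
    with pytest.raises(SeparationError):
        newton_raphson_fit(X, y)
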