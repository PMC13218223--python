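import numpy as np
import pandas as pd
import pytest

from mtslm import FitResult, SplineSpec, generate_dataset, sim_study_preset

# Published 95% interval table of the four-predictor HDI application
# (clean water access, poverty rate, unemployment rate, school enrollment),
# used as printed-value input for interpretation/inference arithmetic.
HDI_TABLE = pd.DataFrame(
    [
        ("intercept", -7.0936, -12.8966, -1.2906, True),
        ("x1", 0.0345, 0.0124, 0.0566, True),
        ("(x1-91.13)+", -0.0151, -0.1403, 0.1101, False),
        ("x2", -0.2190, -0.4039, -0.0341, True),
        ("(x2-9.53)+", -0.0035, -0.2498, 0.2428, False),
        ("x3", 0.9034, 0.5083, 1.2985, True),
        ("(x3-4.05)+", -0.9208, -1.4760, -0.3656, True),
        ("x4", 0.0582, -0.0383, 0.1548, False),
        ("(x4-58.652)+", -0.1101, -0.4685, 0.2484, False),
        ("(x4-62.578)+", 1.1200, 0.0841, 2.1558, True),
        ("(x4-64.518)+", -1.4327, -2.6122, -0.2531, True),
        ("(x4-67.634)+", 0.6041, 0.0463, 1.1620, True),
    ],
    columns=["parameter", "estimate", "lower", "upper", "significant"],
)

HDI_SPEC = SplineSpec(
    degree=1,
    knots={
        "x1": (91.13,),
        "x2": (9.53,),
        "x3": (4.05,),
        "x4": (58.652, 62.578, 64.518, 67.634),
    },
    predictor_names=("x1", "x2", "x3", "x4"),
)


def make_fit(beta, spec=None, n_obs=500):
    """FitResult wrapper around a fixed coefficient vector (identity cov)."""
    beta = np.asarray(beta, dtype=float)
    return FitResult(
        beta=beta,
        covariance=np.eye(beta.size),
        log_likelihood=-1.0,
        n_params=beta.size,
        iterations=1,
        converged=True,
        n_obs=n_obs,
        param_names=tuple(spec.column_labels()) if spec is not None else (),
    )


@pytest.fixture(scope="session")
def hdi_fit():
    return make_fit(HDI_TABLE["estimate"].to_numpy(), spec=HDI_SPEC)


@pytest.fixture(scope="session")
def preset():
    return sim_study_preset()


@pytest.fixture(scope="session")
def preset_dataset(preset):
    spec, beta = preset
    return generate_dataset(200, spec, beta, seed=11)
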