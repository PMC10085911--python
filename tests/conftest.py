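import numpy as np
import pytest
import warnings

from hypothesis import settings, HealthCheck

from claviage.simulate import SimulationParams, simulate_cohort
from claviage.transition import CumulativeProbitTA

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model_cohort():
    """A jitter-free cohort drawn exactly from the generating probit model."""
    params = SimulationParams(n_subjects=600, seed=321, side_jitter=0.0)
    return params, simulate_cohort(params)


@pytest.fixture(scope="session")
def fitted(model_cohort):
    params, cohort = model_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = CumulativeProbitTA(
            cohort["group_L"], cohort["age"], transform="log"
        ).fit()
    return params, cohort, results


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
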