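import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from glymph import PhantomSpec, default_sem_params, generate_cohort, generate_study

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params():
    return default_sem_params(seed=7)


@pytest.fixture(scope="session")
def positive_cohort(default_params):
    return generate_cohort(default_params)


@pytest.fixture(scope="session")
def study_cohort(default_params):
    return generate_study(default_params)


@pytest.fixture(scope="session")
def noiseless_phantom():
    from glymph import generate_tensor_phantom

    spec = PhantomSpec(alps_truth=1.355, noise_sd=0.0)
    vol, truth = generate_tensor_phantom(spec)
    return vol, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
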