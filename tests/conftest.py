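import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from twostep import ParameterSet, TaskConfig, simulate_session

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    """A typical hybrid agent (values near the study's group means)."""
    return ParameterSet(
        omega=0.6, alpha1=0.5, alpha2=0.6, lam=0.65, beta1=5.0, beta2=4.0, rho=0.2
    )


@pytest.fixture(scope="session")
def session(params):
    """One simulated 201-trial session."""
    return simulate_session(params, TaskConfig(), seed=7)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
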