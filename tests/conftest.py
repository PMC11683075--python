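import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from hrlsim import HomeostaticSpace, build_intake_task, build_mountain_task

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def space():
    """Default 1-D homeostatic space: H* = 200, (m, n) = (3, 4), tau = 100."""
    return HomeostaticSpace(setpoint=200.0, m=3.0, n=4.0, eta=1.0, tau=100.0)


@pytest.fixture
def intake_task():
    return build_intake_task(k_intake=16.0, episode_length=100)


@pytest.fixture
def mountain_task():
    return build_mountain_task(k_small=0.8, k_large=110.0, climb_cost=0.3,
                               step_cap=5000)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
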