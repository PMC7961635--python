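import numpy as np
import pytest
from hypothesis import settings

from rtmsk.synthetic import GaitParams, generate_gait_trajectory, make_fixture

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pendulum():
    return make_fixture("pendulum")


@pytest.fixture(scope="session")
def double_pendulum():
    return make_fixture("double_pendulum")


@pytest.fixture(scope="session")
def walker():
    return make_fixture("planar_walker")


@pytest.fixture(scope="session")
def gait_params():
    return GaitParams()


@pytest.fixture(scope="session")
def gait_states(walker, gait_params):
    """3 s of noise-free walking at 100 Hz with analytic derivatives."""
    return generate_gait_trajectory(walker, gait_params, 100.0, 3.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
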