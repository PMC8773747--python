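import numpy as np
import pytest

from nirstress import ChannelLayout, SimulationParams, build_session_schedule


@pytest.fixture(scope="session")
def layout():
    return ChannelLayout()


@pytest.fixture(scope="session")
def schedule_s1():
    return build_session_schedule(1, seed=0)


@pytest.fixture(scope="session")
def schedule_s2():
    return build_session_schedule(2, seed=0)


@pytest.fixture(scope="session")
def noiseless_params():
    return SimulationParams().noiseless()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
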