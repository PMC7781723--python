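import pytest
from hypothesis import HealthCheck, settings

import hemoshock as hs

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session", params=[1, 2, 3, 4])
def subject(request):
    """Each packaged calibrated swine configuration in turn."""
    return hs.load_subject(request.param)


@pytest.fixture(scope="session")
def subject1():
    return hs.load_subject(1)


@pytest.fixture(scope="session")
def subject2():
    return hs.load_subject(2)


@pytest.fixture(scope="session")
def subject1_trajectory(subject1):
    """Full 500-min hemorrhage run for subject 1, shared across tests."""
    return hs.simulate(subject1.parameters, subject1.protocol, subject1.grid)


@pytest.fixture(scope="session")
def short_grid():
    """A 100-min grid covering baseline, bleed and early recovery."""
    return hs.SimulationGrid(t0=0.0, t_end=100.0, t_delta=0.01)
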