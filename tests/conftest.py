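import numpy as np
import pytest

from npbddm.bounds import BoundCurve
from npbddm.ddm_sim import DDMParams, simulate_phase
from npbddm.trial_data import TaskConfig, filter_standard_trials


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def theta():
    """Participant-like drift/non-decision parameters."""
    return DDMParams(kappa=16.19, mu_nd=0.27, sigma_nd=0.02)


@pytest.fixture(scope="session")
def collapsing_bound():
    return BoundCurve.linear_collapse(1.0, 0.15, 5.0, dt=0.001)


@pytest.fixture(scope="session")
def task():
    return TaskConfig()


@pytest.fixture(scope="session")
def session_records(theta, collapsing_bound, task):
    """One simulated no-deadline session (shared across tests)."""
    rng = np.random.default_rng(2024)
    return simulate_phase(theta, collapsing_bound, task, 1500, rng, dt=0.001)


@pytest.fixture(scope="session")
def standard_trials(session_records):
    return filter_standard_trials(session_records)
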