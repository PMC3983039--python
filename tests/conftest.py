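import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from radcell.model import communication_model, integrate, memory_model

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# canonical parameter sets used throughout: continuous low-dose exposure at
# alpha=0.1 with p=0.05, c=1, eta=0.01, from 100 healthy cells
FIG_MEMORY = dict(alpha=0.1, p=0.05, c=1.0, eta=0.01)
FIG_COMM_BETA0 = 10.0
K = 100.0
X0 = (K, 0.0, 0.0, 0.0)


def log_grid(t_end, n=800):
    return np.concatenate([[0.0], np.geomspace(1e-3, t_end, n)])


@pytest.fixture(scope="session")
def memory_params():
    return memory_model(**FIG_MEMORY)


@pytest.fixture(scope="session")
def comm_params():
    return communication_model(**FIG_MEMORY, beta0=FIG_COMM_BETA0)


@pytest.fixture(scope="session")
def memory_traj(memory_params):
    """Continuous exposure, memory model, to t = 1e5 (all cells altered)."""
    return integrate(memory_params, X0, log_grid(1e5))


@pytest.fixture(scope="session")
def comm_traj(comm_params):
    """Continuous exposure, communication model, to t = 1e6 (past the QSS)."""
    return integrate(comm_params, X0, log_grid(1e6))
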