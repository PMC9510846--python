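import numpy as np
import pytest

from bpsweep import BPParams, GridSpec, Trajectory, simulate_bp
from bpsweep.bp import logistic_solution
from bpsweep.recovery import CENTER_PARAMS, DEFAULT_V0, default_schedule


@pytest.fixture(scope="session")
def logistic_params() -> BPParams:
    # Verhulst special case: carrying capacity p/q = 10
    return BPParams(p=0.1, q=0.01, a=1.0, b=2.0)


@pytest.fixture(scope="session")
def logistic_traj(logistic_params) -> Trajectory:
    """Densely sampled noiseless logistic growth, v0 = 1, capacity 10."""
    t = np.linspace(0.0, 114.0, 120)
    return Trajectory(t, logistic_solution(logistic_params.p, logistic_params.q, 1.0, t))


@pytest.fixture(scope="session")
def center_traj() -> Trajectory:
    """Default 14-point synthetic tumor from the published best-fit parameters."""
    return simulate_bp(CENTER_PARAMS, DEFAULT_V0, default_schedule())


@pytest.fixture(scope="session")
def recovery_grid() -> GridSpec:
    """The coarse exponent grid over the recovery region 1.0 <= a, b <= 3.0."""
    return GridSpec(step=0.05, b_max=3.0, a_min=1.0)
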