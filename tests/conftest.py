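import warnings

import numpy as np
import pytest

from pupilhgf import HGFParams, generate_schedule, simulate_agent_responses

# BFGS probing unstable parameter regions emits benign invalid-value warnings
warnings.filterwarnings("ignore", message="invalid value encountered",
                        category=RuntimeWarning)


@pytest.fixture(scope="session")
def schedule():
    return generate_schedule(seed=11)


@pytest.fixture(scope="session")
def agent(schedule):
    """One simulated participant: (u, y, generating trajectory, params)."""
    params = HGFParams(omega=-4.8, zeta=3.0)
    y, traj = simulate_agent_responses(schedule, params, seed=21)
    return schedule.u, y, traj, params


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
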