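import math

import numpy as np
import pytest

from twitchsim.engine import init_configuration
from twitchsim.kinematics import SystemState
from twitchsim.params import Phase, SimulationParams


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)


def make_rod_state(
    params: SimulationParams,
    centers,
    angles,
    bond=0.935,
    perturb=0.0,
    rng=None,
) -> SystemState:
    """Straight rods at given centres/angles, optionally jittered."""
    rods = []
    for c, th in zip(np.atleast_2d(centers), np.atleast_1d(angles)):
        u = np.array([math.cos(th), math.sin(th)])
        rod = np.asarray(c, float) + (np.arange(4) - 1.5)[:, None] * bond * u
        if perturb and rng is not None:
            rod = rod + rng.normal(0, perturb, rod.shape)
        rods.append(rod)
    unwrapped = np.concatenate(rods)
    pos = np.mod(unwrapped, params.box_L)
    n_tw = len(rods)
    return SystemState(
        pos=pos,
        pos_unwrapped=unwrapped,
        vel=np.zeros_like(pos),
        phase=np.full(n_tw, int(Phase.REST), dtype=np.int8),
        phase_clock=np.zeros(n_tw),
        anchor=np.full((n_tw, 2), np.nan),
    )


@pytest.fixture(scope="session")
def packed_state(rng):
    """A moderately dense overlap-free many-twitcher configuration."""
    p = SimulationParams(total_steps=0, n_twitchers=120, box_L=60.0)
    return p, init_configuration(p, np.random.default_rng(5))
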