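"""Synthetic trajectories with known statistical structure.

These generators produce :class:`~twitchsim.trajectory.Trajectory`
objects whose displacement statistics are known in closed form, and are
the independent fixtures against which the analysis suite is validated:

* ballistic motion: MSD = v^2 t^2, beta = 2;
* Brownian motion with diffusivity D0: MSD = 4 D0 t, alpha_2 = 0;
* fixed-length random-direction steps: alpha_2 = -1/2 at one step (the
  platykurtic lower bound -2/(d+2) for shell-distributed steps);
* a 50/50 mixture of zero steps and Gaussian steps: alpha_2 = 1;
* a persistent random walk with rotational diffusion D_rot: direction
  autocorrelation exp(-D_rot t), decorrelation path length v / D_rot;
* uncorrelated (Poisson-like) and strongly clustered point fields for
  the number-fluctuation exponent (mu = 1/2 and mu -> 1).
"""

from __future__ import annotations

import numpy as np

from .params import twitcher_area
from .trajectory import Trajectory

__all__ = [
    "ballistic",
    "brownian",
    "shell_steps",
    "zero_gaussian_mixture",
    "persistent_walk",
    "uniform_field",
    "clustered_field",
]


def _traj_from_steps(steps: np.ndarray, box_L: float) -> Trajectory:
    com = np.concatenate(
        [np.zeros((1,) + steps.shape[1:]), np.cumsum(steps, axis=0)], axis=0
    )
    com += box_L / 2.0
    return Trajectory(
        times=np.arange(com.shape[0], dtype=float),
        com=com, box_L=box_L, a_twitch=twitcher_area(),
    )


def ballistic(
    speed: float = 1.0,
    n_frames: int = 64,
    n_walkers: int = 1,
    direction=(1.0, 0.0),
    box_L: float = 100.0,
) -> Trajectory:
    """Straight-line motion at constant speed."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    steps = np.broadcast_to(speed * d, (n_frames - 1, n_walkers, 2)).copy()
    return _traj_from_steps(steps, box_L)


def brownian(
    d0: float = 1.0,
    n_frames: int = 1024,
    n_walkers: int = 1,
    box_L: float = 100.0,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """2D Brownian motion: per-frame Gaussian steps, MSD = 4 D0 t."""
    rng = rng or np.random.default_rng(0)
    steps = rng.normal(0.0, np.sqrt(2.0 * d0), size=(n_frames - 1, n_walkers, 2))
    return _traj_from_steps(steps, box_L)


def shell_steps(
    step_length: float = 1.0,
    n_frames: int = 2,
    n_walkers: int = 100_000,
    box_L: float = 100.0,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Independent fixed-length steps in uniformly random directions."""
    rng = rng or np.random.default_rng(0)
    th = rng.uniform(0, 2 * np.pi, size=(n_frames - 1, n_walkers))
    steps = step_length * np.stack([np.cos(th), np.sin(th)], axis=-1)
    return _traj_from_steps(steps, box_L)


def zero_gaussian_mixture(
    sigma: float = 1.0,
    p_zero: float = 0.5,
    n_frames: int = 2,
    n_walkers: int = 100_000,
    box_L: float = 100.0,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Steps that are zero with probability ``p_zero``, else 2D Gaussian."""
    rng = rng or np.random.default_rng(0)
    steps = rng.normal(0.0, sigma, size=(n_frames - 1, n_walkers, 2))
    frozen = rng.random(size=steps.shape[:2]) < p_zero
    steps[frozen] = 0.0
    return _traj_from_steps(steps, box_L)


def persistent_walk(
    speed: float = 1.0,
    d_rot: float = 0.05,
    n_frames: int = 4096,
    n_walkers: int = 8,
    box_L: float = 100.0,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Constant-speed walk whose heading diffuses with coefficient D_rot.

    The direction autocorrelation decays as exp(-D_rot t); expressed
    against path length it decays with length ``speed / d_rot``.
    """
    rng = rng or np.random.default_rng(0)
    dth = rng.normal(0.0, np.sqrt(2.0 * d_rot), size=(n_frames - 1, n_walkers))
    th = np.cumsum(dth, axis=0) + rng.uniform(0, 2 * np.pi, size=(1, n_walkers))
    steps = speed * np.stack([np.cos(th), np.sin(th)], axis=-1)
    return _traj_from_steps(steps, box_L)


def uniform_field(
    n_points: int = 400,
    n_frames: int = 200,
    box_L: float = 100.0,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Points independently re-placed uniformly every frame.

    Window occupancies are binomial, so fluctuations follow the central
    limit scaling DN ~ <N>^(1/2).
    """
    rng = rng or np.random.default_rng(0)
    com = rng.uniform(0, box_L, size=(n_frames, n_points, 2))
    return Trajectory(times=np.arange(n_frames, dtype=float), com=com,
                      box_L=box_L, a_twitch=twitcher_area())


def clustered_field(
    n_points: int = 400,
    n_frames: int = 200,
    box_L: float = 100.0,
    area_fraction_range: tuple[float, float] = (0.05, 0.4),
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """All points confined to one randomly sized and placed cluster.

    Every frame the whole population occupies a single square patch, so
    window occupancies are a common density factor times the window
    area plus counting noise; in the large-occupancy limit the common
    factor dominates and DN ~ <N> (mu -> 1).
    """
    rng = rng or np.random.default_rng(0)
    com = np.empty((n_frames, n_points, 2))
    for f in range(n_frames):
        a = rng.uniform(*area_fraction_range)
        edge = np.sqrt(a) * box_L
        corner = rng.uniform(0, box_L, size=2)
        com[f] = np.mod(corner + rng.uniform(0, edge, size=(n_points, 2)), box_L)
    return Trajectory(times=np.arange(n_frames, dtype=float), com=com,
                      box_L=box_L, a_twitch=twitcher_area())
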