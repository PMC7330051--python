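"""Per-twitcher state and derived kinematic quantities.

Twitcher sphere indexing: twitcher ``g`` owns spheres ``4g .. 4g+3``;
index ``4g`` is the tail and ``4g+3`` the head (the pilus attaches to
the head).  The centre of mass is the mean of the four unwrapped sphere
positions and the per-tau velocity is the centre-of-mass displacement
over one unit time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import Phase, SPHERES_PER_TWITCHER, SimulationParams

__all__ = [
    "SystemState",
    "TwitcherKinematics",
    "derive_kinematics",
    "canonical_nematic",
    "polar_vectors",
    "com_positions",
]


@dataclass
class SystemState:
    """Instantaneous mechanical and motility state of the whole system.

    ``pos`` holds wrapped sphere positions in ``[0, box_L)^2`` and
    ``pos_unwrapped`` the continuous (image-unfolded) positions; the two
    differ by integer multiples of the box edge on each axis.  Per
    twitcher, ``phase`` is the motility phase, ``phase_clock`` the time
    since phase entry (tau units) and ``anchor`` the wrapped pilus
    adhesion point (NaN rows when no pilus is attached; an anchor is
    present exactly while retracting).
    """

    pos: np.ndarray
    pos_unwrapped: np.ndarray
    vel: np.ndarray
    phase: np.ndarray
    phase_clock: np.ndarray
    anchor: np.ndarray
    t: float = 0.0

    @property
    def n_spheres(self) -> int:
        return self.pos.shape[0]

    @property
    def n_twitchers(self) -> int:
        return self.n_spheres // SPHERES_PER_TWITCHER

    def copy(self) -> "SystemState":
        return SystemState(
            self.pos.copy(), self.pos_unwrapped.copy(), self.vel.copy(),
            self.phase.copy(), self.phase_clock.copy(), self.anchor.copy(),
            self.t,
        )

    def check(self, params: SimulationParams) -> None:
        """Raise if structural invariants are violated."""
        if self.pos.shape != self.pos_unwrapped.shape or self.pos.shape != self.vel.shape:
            raise ValueError("position/velocity array shapes disagree")
        if self.n_spheres % SPHERES_PER_TWITCHER:
            raise ValueError("sphere count is not a multiple of 4")
        n = self.n_twitchers
        if not (self.phase.shape == (n,) and self.anchor.shape == (n, 2)):
            raise ValueError("per-twitcher array shapes disagree")
        off = (self.pos_unwrapped - self.pos) / params.box_L
        if not np.allclose(off, np.round(off), atol=1e-8):
            raise ValueError(
                "wrapped and unwrapped positions differ by non-integer box multiples"
            )
        retracting = self.phase == int(Phase.RETRACTION)
        has_anchor = np.isfinite(self.anchor).all(axis=1)
        if not np.array_equal(retracting, has_anchor):
            raise ValueError("anchor must be present exactly while retracting")


@dataclass
class TwitcherKinematics:
    """Derived kinematics of one twitcher over one unit-time interval.

    ``direction`` is ``None`` for a twitcher that did not move (the
    direction of motion is undefined at zero speed and such samples are
    excluded from direction correlators).  ``nematic`` is stored in
    canonical form: the sign is flipped so that the x-component is
    non-negative (ties broken toward non-negative y), making the
    headless director a single-valued quantity.
    """

    com: np.ndarray
    velocity: np.ndarray
    speed: float
    direction: np.ndarray | None
    polar: np.ndarray
    nematic: np.ndarray


def com_positions(pos_unwrapped: np.ndarray) -> np.ndarray:
    """Centre of mass of each twitcher from unwrapped sphere positions."""
    n = pos_unwrapped.shape[0] // SPHERES_PER_TWITCHER
    return pos_unwrapped.reshape(n, SPHERES_PER_TWITCHER, 2).mean(axis=1)


def polar_vectors(pos_unwrapped: np.ndarray) -> np.ndarray:
    """Unit tail-to-head orientation of each twitcher."""
    n = pos_unwrapped.shape[0] // SPHERES_PER_TWITCHER
    r = pos_unwrapped.reshape(n, SPHERES_PER_TWITCHER, 2)
    d = r[:, -1] - r[:, 0]
    norm = np.linalg.norm(d, axis=1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("degenerate twitcher with coincident head and tail")
    return d / norm


def canonical_nematic(p: np.ndarray) -> np.ndarray:
    """Map a director (or array of directors) to its canonical sign.

    ``n`` and ``-n`` represent the same nematic orientation; the stored
    representative has ``n_x >= 0``, with ``n_y >= 0`` when ``n_x == 0``.
    """
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    q = np.atleast_2d(p).copy()
    flip = (q[:, 0] < 0) | ((q[:, 0] == 0) & (q[:, 1] < 0))
    q[flip] *= -1.0
    return q[0] if single else q


def derive_kinematics(
    state: SystemState,
    prev_state: SystemState,
    params: SimulationParams | None = None,
) -> list[TwitcherKinematics]:
    """Kinematics of every twitcher from two states one tau apart.

    The velocity is the centre-of-mass displacement between the two
    states divided by tau; the polar vector is taken from the later
    state.
    """
    p = params or SimulationParams(total_steps=0)
    if state.n_spheres != prev_state.n_spheres:
        raise ValueError("states hold different numbers of twitchers")
    tau = p.tau
    com_now = com_positions(state.pos_unwrapped)
    com_prev = com_positions(prev_state.pos_unwrapped)
    vel = (com_now - com_prev) / tau
    speed = np.linalg.norm(vel, axis=1)
    pol = polar_vectors(state.pos_unwrapped)
    nem = canonical_nematic(pol)
    out = []
    for g in range(state.n_twitchers):
        v = speed[g]
        out.append(
            TwitcherKinematics(
                com=com_now[g],
                velocity=vel[g],
                speed=float(v),
                direction=(vel[g] / v) if v > 0 else None,
                polar=pol[g],
                nematic=nem[g],
            )
        )
    return out
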