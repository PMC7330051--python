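"""In-memory trajectory of per-twitcher observables.

A :class:`Trajectory` carries frames sampled every unit time tau: the
unwrapped centre of mass, the polar orientation and the motility phase
of every twitcher.  All analysis (displacement statistics, correlators,
coverage fields) operates on this container, whether it was produced
directly by the engine or read back from a trajectory file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinematics import canonical_nematic
from .params import SimulationParams, twitcher_area

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """Time-ordered per-twitcher frames sampled every tau.

    Attributes
    ----------
    times:
        Frame times, shape (F,), strictly increasing by the frame
        interval.
    com:
        Unwrapped centre-of-mass positions, shape (F, N, 2).
    polar:
        Unit tail-to-head orientations, shape (F, N, 2), or None for
        synthetic point trajectories.
    phase:
        Motility phase codes per frame and twitcher (F, N), or None.
    box_L:
        Periodic box edge.
    a_twitch:
        Footprint area of one twitcher, used by coverage statistics.
    """

    times: np.ndarray
    com: np.ndarray
    polar: np.ndarray | None = None
    phase: np.ndarray | None = None
    box_L: float = 100.0
    a_twitch: float = twitcher_area()
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.com = np.asarray(self.com, dtype=float)
        if self.com.ndim != 3 or self.com.shape[2] != 2:
            raise ValueError("com must have shape (frames, twitchers, 2)")
        if self.times.shape[0] != self.com.shape[0]:
            raise ValueError("times and com frame counts disagree")
        if self.times.size > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("frame times must be strictly increasing")

    # ------------------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.com.shape[0]

    @property
    def n_twitchers(self) -> int:
        return self.com.shape[1]

    @property
    def frame_dt(self) -> float:
        if self.n_frames < 2:
            return 1.0
        return float(self.times[1] - self.times[0])

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])

    def com_wrapped(self) -> np.ndarray:
        return np.mod(self.com, self.box_L)

    # ------------------------------------------------------------------
    def velocities(self) -> np.ndarray:
        """Per-interval velocity (F-1, N, 2), displacement over one frame."""
        return np.diff(self.com, axis=0) / self.frame_dt

    def speeds(self) -> np.ndarray:
        return np.linalg.norm(self.velocities(), axis=2)

    def directions(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit directions of motion and a validity mask (F-1, N).

        The direction is undefined (mask False, vector zeroed) wherever
        the twitcher did not move during the interval.
        """
        v = self.velocities()
        s = np.linalg.norm(v, axis=2)
        ok = s > 0
        d = np.zeros_like(v)
        np.divide(v, s[..., None], out=d, where=ok[..., None])
        return d, ok

    def nematic(self) -> np.ndarray:
        """Canonical directors per frame (F, N, 2)."""
        if self.polar is None:
            raise ValueError("trajectory carries no orientation data")
        f, n, _ = self.polar.shape
        return canonical_nematic(self.polar.reshape(-1, 2)).reshape(f, n, 2)

    def steady_slice(self, warmup_frac: float = 0.1) -> "Trajectory":
        """Drop the first ``warmup_frac`` of frames (equilibration)."""
        k = int(np.floor(warmup_frac * self.n_frames))
        return Trajectory(
            self.times[k:], self.com[k:],
            None if self.polar is None else self.polar[k:],
            None if self.phase is None else self.phase[k:],
            self.box_L, self.a_twitch, dict(self.meta),
        )

    @property
    def coverage(self) -> float:
        return self.n_twitchers * self.a_twitch / self.box_L**2

    @classmethod
    def from_params(cls, params: SimulationParams, n_frames: int) -> "Trajectory":
        """Pre-allocated empty trajectory for ``n_frames`` frames."""
        n = params.n_twitchers
        return cls(
            times=np.arange(n_frames, dtype=float) * params.tau,
            com=np.zeros((n_frames, n, 2)),
            polar=np.zeros((n_frames, n, 2)),
            phase=np.zeros((n_frames, n), dtype=np.int8),
            box_L=params.box_L,
            a_twitch=twitcher_area(params),
            meta={"n_twitchers": n, "seed": params.seed},
        )
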