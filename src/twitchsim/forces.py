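"""Conservative force field of the twitcher model.

Four contributions act on the spheres:

* WCA excluded volume between *all* sphere pairs (bonded neighbours
  included), ``V = 4 eps [(s/r)^12 - (s/r)^6] + eps`` for ``r < 2^(1/6) s``;
* FENE bonds between consecutive spheres of a body,
  ``V = -1/2 kF R0^2 ln(1 - (r/R0)^2)``;
* harmonic angle rigidity about ``theta_0 = pi`` for each triple of
  sequential spheres, ``V = kH (theta - theta_0)^2 / 2``;
* during retraction, a constant-magnitude pilus force pulling the head
  sphere toward its anchor, cut off below ``r_0``.

The scalar functions here are plain-Python references used for testing
and documentation; the production path is the numba kernel behind
:func:`total_forces`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .kinematics import SystemState
from .params import SPHERES_PER_TWITCHER, SimulationParams

__all__ = [
    "BondOverstretchError",
    "wca",
    "fene",
    "angle_energy",
    "angle_harmonic",
    "pilus_force",
    "ForceField",
    "total_forces",
    "total_energy",
    "minimum_image",
]


class BondOverstretchError(RuntimeError):
    """A FENE bond reached its maximum extension R0."""


def minimum_image(d: np.ndarray, box_L: float) -> np.ndarray:
    """Nearest periodic image of a separation vector (or array of them)."""
    d = np.asarray(d, dtype=float)
    return d - box_L * np.round(d / box_L)


def _p(params: SimulationParams | None) -> SimulationParams:
    return params or SimulationParams(total_steps=0)


def wca(r: float, params: SimulationParams | None = None) -> tuple[float, float]:
    """WCA pair energy and radial force ``F = -dV/dr`` at separation r.

    The force is non-negative (purely repulsive) and continuous at the
    cut-off ``r_c = 2^(1/6) sigma``.
    """
    p = _p(params)
    if r <= 0:
        raise ValueError("separation must be positive")
    if r >= p.wca_cutoff:
        return 0.0, 0.0
    eps, s = p.energy_scale, p.sphere_size
    sr6 = (s / r) ** 6
    v = 4.0 * eps * (sr6 * sr6 - sr6) + eps
    f = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r
    return v, f


def fene(r: float, params: SimulationParams | None = None) -> tuple[float, float]:
    """FENE bond energy and radial force ``F = -dV/dr``.

    The force is negative (attractive) for r > 0 and diverges as the
    bond approaches its maximum extension ``R0``, where a
    :class:`BondOverstretchError` is raised.
    """
    p = _p(params)
    if r < 0:
        raise ValueError("separation must be non-negative")
    if r >= p.fene_R0:
        raise BondOverstretchError(
            f"bond length {r:.6g} reached the FENE maximum R0={p.fene_R0:.6g}"
        )
    x = (r / p.fene_R0) ** 2
    v = -0.5 * p.fene_kF * p.fene_R0**2 * math.log(1.0 - x)
    f = -p.fene_kF * r / (1.0 - x)
    return v, f


def angle_energy(theta: float, params: SimulationParams | None = None) -> float:
    """Harmonic bending energy ``kH (theta - theta_0)^2 / 2``."""
    p = _p(params)
    return 0.5 * p.angle_kH * (theta - p.angle_theta0) ** 2


def angle_harmonic(
    x_i: np.ndarray,
    x_j: np.ndarray,
    x_k: np.ndarray,
    params: SimulationParams | None = None,
    box_L: float | None = None,
) -> tuple[float, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Bending energy and forces for the sequential triple (i, j, k).

    ``j`` is the vertex.  The returned forces are the negative gradient
    distributed over the three spheres; their sum and the net torque
    about the vertex both vanish.
    """
    p = _p(params)
    L = box_L if box_L is not None else p.box_L
    d1 = minimum_image(np.asarray(x_i, float) - np.asarray(x_j, float), L)
    d2 = minimum_image(np.asarray(x_k, float) - np.asarray(x_j, float), L)
    r1 = np.linalg.norm(d1)
    r2 = np.linalg.norm(d2)
    if r1 == 0.0 or r2 == 0.0:
        raise ValueError("degenerate zero-length bond vector in angle term")
    c = float(np.clip(np.dot(d1, d2) / (r1 * r2), -1.0, 1.0))
    s = max(math.sqrt(1.0 - c * c), 1e-12)
    theta = math.acos(c)
    v = angle_energy(theta, p)
    a = p.angle_kH * (theta - p.angle_theta0) / s
    f_i = a * (d2 / (r1 * r2) - c * d1 / r1**2)
    f_k = a * (d1 / (r1 * r2) - c * d2 / r2**2)
    f_j = -(f_i + f_k)
    return v, (f_i, f_j, f_k)


def pilus_force(
    head_pos: np.ndarray,
    anchor: np.ndarray,
    params: SimulationParams | None = None,
) -> np.ndarray:
    """Constant-magnitude retraction force on the head sphere.

    The head is pulled toward the anchor with force ``k_P`` whenever the
    minimum-image head-anchor distance exceeds the cut-off ``r_0``;
    inside the cut-off the force is zero (arrival itself is handled by
    the motility cycle at ``L_R``).
    """
    p = _p(params)
    if anchor is None or not np.all(np.isfinite(anchor)):
        raise ValueError("pilus force requested without an anchor")
    d = minimum_image(np.asarray(anchor, float) - np.asarray(head_pos, float), p.box_L)
    r = float(np.linalg.norm(d))
    if r <= p.pilus_r0:
        return np.zeros(2)
    return p.pilus_kP * d / r


@dataclass
class ForceField:
    """Interaction topology: bonds and angle triples per twitcher.

    Bonds join consecutive spheres (3 per twitcher) and angles span
    consecutive triples (2 per twitcher); both connect only spheres of
    the same body.  WCA needs no list since it acts between all pairs.
    """

    params: SimulationParams
    bonds: np.ndarray
    angles: np.ndarray

    @classmethod
    def for_twitchers(cls, n_twitchers: int, params: SimulationParams | None = None) -> "ForceField":
        p = _p(params)
        bonds = []
        angles = []
        for g in range(n_twitchers):
            b = SPHERES_PER_TWITCHER * g
            bonds += [(b + k, b + k + 1) for k in range(3)]
            angles += [(b + k, b + k + 1, b + k + 2) for k in range(2)]
        return cls(
            params=p,
            bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
            angles=np.asarray(angles, dtype=np.int64).reshape(-1, 3),
        )


def _cell_arrays(n: int, box_L: float, use_cells: bool):
    if use_cells:
        ncell = max(int(box_L // 1.5), 1)
    else:
        ncell = 1
    head = np.empty(ncell * ncell, dtype=np.int64)
    nxt = np.empty(max(n, 1), dtype=np.int64)
    return ncell, head, nxt


def should_use_cells(n_spheres: int, box_L: float) -> bool:
    """Cell lists pay off once the box holds enough spheres."""
    return n_spheres >= 100 and int(box_L // 1.5) >= 4


def total_forces(
    state: SystemState,
    ff: ForceField | None = None,
    params: SimulationParams | None = None,
    use_cells: bool | None = None,
) -> np.ndarray:
    """Total conservative force on every sphere of ``state``.

    Sums WCA over all pairs within the cut-off (minimum image), FENE
    over the bond list, bending over the angle list, and the pilus force
    on the heads of retracting twitchers.
    """
    p = params or (ff.params if ff is not None else None) or _p(None)
    pos = np.ascontiguousarray(state.pos, dtype=np.float64)
    n = pos.shape[0]
    if use_cells is None:
        use_cells = should_use_cells(n, p.box_L)
    ncell, head, nxt = _cell_arrays(n, p.box_L, use_cells)
    f = np.zeros_like(pos)
    err = _kernels.compute_forces(
        pos, f, p.box_L, state.phase.astype(np.int8),
        np.ascontiguousarray(state.anchor, dtype=np.float64),
        p.energy_scale, p.sphere_size, p.wca_cutoff,
        p.fene_kF, p.fene_R0, p.angle_kH, p.angle_theta0,
        p.pilus_kP, p.pilus_r0,
        use_cells, head, nxt, ncell,
    )
    if err == _kernels.ERR_OVERSTRETCH:
        raise BondOverstretchError("a FENE bond reached its maximum extension R0")
    if err == _kernels.ERR_DEGENERATE:
        raise ValueError("degenerate zero-length bond vector")
    return f


def total_energy(state: SystemState, params: SimulationParams | None = None) -> float:
    """Total potential energy of ``state`` (WCA + FENE + angle + pilus)."""
    p = _p(params)
    return float(
        _kernels.total_energy(
            np.ascontiguousarray(state.pos, dtype=np.float64),
            p.box_L, state.phase.astype(np.int8),
            np.ascontiguousarray(state.anchor, dtype=np.float64),
            p.energy_scale, p.sphere_size, p.wca_cutoff,
            p.fene_kF, p.fene_R0, p.angle_kH, p.angle_theta0,
            p.pilus_kP, p.pilus_r0,
        )
    )


def equilibrium_bond_length(params: SimulationParams | None = None) -> float:
    """Bond length at which the WCA repulsion balances the FENE pull.

    With the default stiffnesses this sits near 0.96-0.97 sigma.
    """
    from scipy.optimize import brentq

    p = _p(params)

    def net(r):
        return wca(r, p)[1] + fene(r, p)[1]

    return float(brentq(net, 0.8 * p.sphere_size, p.wca_cutoff - 1e-9))
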