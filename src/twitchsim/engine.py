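"""Langevin integration loop, initial configurations and `simulate`.

The equation of motion per sphere is ``m x'' = -zeta x' - grad V + xi``
with Gaussian noise obeying the fluctuation-dissipation relation at the
(nearly zero) bath temperature.  Integration uses the
Gronbech-Jensen/Farago discretisation, which handles the linear drag
exactly; with ``m/zeta = tau`` and ``dt = 0.01 tau`` the scheme is
comfortably stable.  Positions are kept both wrapped (for forces and
neighbour search) and unwrapped (for displacement statistics).

One frame is sampled per unit time tau - the analysis definitions of
velocity and direction of motion require exactly this cadence.
"""

from __future__ import annotations

import math
import time as _time
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .forces import BondOverstretchError, equilibrium_bond_length, should_use_cells
from .kinematics import SystemState, polar_vectors
from .motility import EVENT_KINDS, MotilityEvent, boundary_update
from .params import Phase, SPHERES_PER_TWITCHER, SimulationParams, coverage_fraction
from .trajectory import Trajectory

__all__ = [
    "SimulationError",
    "RunReport",
    "init_configuration",
    "simulate",
    "retraction_arrival_time",
]

#: Pair energy above which a trial insertion counts as an overlap.
_INSERT_ENERGY_CAP = 10.0


class SimulationError(RuntimeError):
    """Integration failed (non-finite positions or overstretched bond)."""


@dataclass
class RunReport:
    """Book-keeping summary of one simulate() call."""

    seed: int
    params: SimulationParams
    frames: int
    event_counts: dict = field(default_factory=dict)
    events: list = field(default_factory=list)
    wall_clock: float = 0.0
    final_state: SystemState | None = None


# ----------------------------------------------------------------------
# Initial configurations
# ----------------------------------------------------------------------

def _overlap_radius(params: SimulationParams) -> float:
    """Separation below which the WCA pair energy exceeds the cap."""
    from scipy.optimize import brentq
    from .forces import wca

    return float(
        brentq(
            lambda r: wca(r, params)[0] - _INSERT_ENERGY_CAP,
            0.5 * params.sphere_size,
            params.wca_cutoff - 1e-9,
        )
    )


def _rod_positions(center, angle, b0):
    u = np.array([math.cos(angle), math.sin(angle)])
    offsets = (np.arange(SPHERES_PER_TWITCHER) - 1.5)[:, None] * b0 * u
    return center + offsets


def _fresh_state(params: SimulationParams, pos: np.ndarray) -> SystemState:
    # ``pos`` is continuous (pre-wrap): bodies crossing a boundary must
    # keep coherent unwrapped coordinates or their centre of mass and
    # orientation would be wrong from the first frame on
    n_tw = params.n_twitchers
    pos = np.asarray(pos, dtype=float)
    return SystemState(
        pos=np.mod(pos, params.box_L),
        pos_unwrapped=pos.copy(),
        vel=np.zeros_like(pos),
        phase=np.full(n_tw, int(Phase.REST), dtype=np.int8),
        phase_clock=np.zeros(n_tw),
        anchor=np.full((n_tw, 2), np.nan),
        t=0.0,
    )


def _recohere_unwrapped(state: SystemState, box_L: float) -> None:
    """Rebuild continuous coordinates from wrapped ones, per twitcher."""
    pos = state.pos
    unw = np.empty_like(pos)
    for g in range(state.n_twitchers):
        b = SPHERES_PER_TWITCHER * g
        unw[b] = pos[b]
        for k in range(1, SPHERES_PER_TWITCHER):
            d = pos[b + k] - pos[b + k - 1]
            d -= box_L * np.round(d / box_L)
            unw[b + k] = unw[b + k - 1] + d
    state.pos_unwrapped = unw


def init_configuration(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> SystemState:
    """Place N straight twitchers without overlaps, all resting.

    Random sequential insertion of rods (random position and
    orientation) is used for coverage up to 0.3; denser systems start
    from an aligned lattice with random polarity followed by a
    1000-tau randomising warm-up, after which phases are reset to REST
    and the unwrapped origin is re-zeroed.
    """
    rng = rng or np.random.default_rng(params.seed)
    n = params.n_twitchers
    phi = coverage_fraction(n, params)
    if phi > 0.8:
        raise ValueError(f"requested coverage {phi:.3f} exceeds the supported 0.8")
    if n == 0:
        return _fresh_state(params, np.zeros((0, 2)))
    b0 = equilibrium_bond_length(params)
    L = params.box_L

    if phi <= 0.3:
        r_min = _overlap_radius(params)
        placed = np.empty((0, 2))
        rods = []
        attempts_budget = 300 * n + 1000
        attempts = 0
        for _ in range(n):
            while True:
                attempts += 1
                if attempts > attempts_budget:
                    raise SimulationError(
                        "random insertion failed after "
                        f"{attempts_budget} attempts at coverage {phi:.3f}; "
                        "use the lattice initialisation (coverage > 0.3 path)"
                    )
                rod = _rod_positions(rng.uniform(0, L, size=2),
                                     rng.uniform(0, 2 * math.pi), b0)
                # overlap check against already-placed spheres (min image)
                if placed.size:
                    d = rod[:, None, :] - placed[None, :, :]
                    d -= L * np.round(d / L)
                    if np.any(np.einsum("ijk,ijk->ij", d, d) < r_min**2):
                        continue
                rods.append(rod)
                placed = np.concatenate([placed, np.mod(rod, L)])
                break
        return _fresh_state(params, np.concatenate(rods))

    # ---- aligned lattice with random polarity + randomising warm-up --
    nx = int(L // 4.0)
    ny = int(math.ceil(n / nx))
    if ny > int(L // 1.0):
        raise SimulationError(
            f"cannot fit {n} twitchers on the lattice in a box of edge {L}"
        )
    sx, sy = L / nx, L / ny
    rods = []
    k = 0
    for iy in range(ny):
        for ix in range(nx):
            if k >= n:
                break
            sign = 1.0 if rng.random() < 0.5 else -1.0
            center = np.array([(ix + 0.5) * sx, (iy + 0.5) * sy])
            rods.append(_rod_positions(center, 0.0 if sign > 0 else math.pi, b0))
            k += 1
    state = _fresh_state(params, np.concatenate(rods))

    warm = params.replace(total_steps=1000 * params.steps_per_tau)
    _run(warm, state, rng, record=None)
    # reset the motility cycle and the unwrapped origin: the warm-up
    # only serves to randomise positions and orientations
    state.phase[:] = int(Phase.REST)
    state.phase_clock[:] = 0.0
    state.anchor[:] = np.nan
    _recohere_unwrapped(state, params.box_L)
    state.t = 0.0
    return state


# ----------------------------------------------------------------------
# Core loop
# ----------------------------------------------------------------------

#: Verlet-list skin (length units); pairs are gathered out to
#: cut-off + skin and the list is rebuilt once any sphere has moved
#: half a skin.
_SKIN = 0.4


def _run(
    params: SimulationParams,
    state: SystemState,
    rng: np.random.Generator,
    record: Trajectory | None,
    noise_rng: np.random.Generator | None = None,
    writer=None,
    events: list | None = None,
    t_offset: float = 0.0,
):
    """Advance ``params.n_tau`` unit times in place; optionally record."""
    p = params
    n = state.n_spheres
    n_tw = state.n_twitchers
    pos = np.ascontiguousarray(state.pos)
    posu = np.ascontiguousarray(state.pos_unwrapped)
    vel = np.ascontiguousarray(state.vel)
    phase = np.ascontiguousarray(state.phase, dtype=np.int8)
    anchor = np.ascontiguousarray(state.anchor)
    if noise_rng is None:
        noise_rng = rng.spawn(1)[0]
    f0 = np.zeros_like(pos)
    f1 = np.zeros_like(pos)
    retr_clock = np.zeros(n_tw, dtype=np.int64)
    # phase entry times in tau units, relative to t_offset
    phase_entry = np.full(n_tw, t_offset) - state.phase_clock
    use_cells = should_use_cells(n, p.box_L)
    ncell = max(int(p.box_L // 1.5), 1) if use_cells else 1
    head = np.empty(ncell * ncell, dtype=np.int64)
    nxt = np.empty(max(n, 1), dtype=np.int64)
    pairs_i = np.empty(24 * n + 64, dtype=np.int64)
    pairs_j = np.empty(24 * n + 64, dtype=np.int64)
    pair_ref = np.empty_like(pos)
    zero_noise = np.zeros((p.steps_per_tau, max(n, 1), 2))
    noise_buf = np.empty((p.steps_per_tau, max(n, 1), 2))
    ev_tid = np.empty(max(n_tw, 1), dtype=np.int64)
    ev_kind = np.empty(max(n_tw, 1), dtype=np.int64)
    ev_step = np.empty(max(n_tw, 1), dtype=np.int64)
    tM_steps = int(round(p.exhaust_tM / p.dt))

    counts = {k: 0 for k in EVENT_KINDS}

    def _record(idx: int, t: float):
        if record is not None:
            record.times[idx] = t
            record.com[idx] = posu.reshape(n_tw, SPHERES_PER_TWITCHER, 2).mean(axis=1)
            record.polar[idx] = polar_vectors(posu)
            record.phase[idx] = phase
        if writer is not None:
            writer.write_frame_arrays(t, pos, posu, phase, anchor, p)

    _record(0, t_offset)
    for k in range(p.n_tau):
        t_now = t_offset + k * p.tau
        evs = boundary_update(
            phase, phase_entry, anchor, retr_clock, pos, posu,
            t_now, p, rng,
        )
        for e in evs:
            counts[e.kind] += 1
        if events is not None:
            events.extend(evs)
        if p.temperature > 0.0 and n > 0:
            noise_rng.standard_normal(out=noise_buf)
            noise = noise_buf
        else:
            noise = zero_noise
        nev, err, err_step = _kernels.advance(
            pos, posu, vel, f0, f1, phase, anchor, retr_clock,
            p.steps_per_tau, k * p.steps_per_tau, noise,
            p.box_L, p.dt, p.sphere_mass, p.friction, p.temperature,
            p.energy_scale, p.sphere_size, p.wca_cutoff, _SKIN,
            p.fene_kF, p.fene_R0, p.angle_kH, p.angle_theta0,
            p.pilus_kP, p.pilus_r0,
            p.arrive_LR, p.snap_LS, tM_steps,
            use_cells, head, nxt, ncell,
            pairs_i, pairs_j, pair_ref,
            ev_tid, ev_kind, ev_step,
        )
        if err == _kernels.ERR_OVERSTRETCH:
            raise BondOverstretchError(
                f"FENE bond overstretched at integration step {err_step}"
            )
        if err != _kernels.ERR_NONE:
            raise SimulationError(f"force evaluation failed at step {err_step}")
        for j in range(nev):
            kind = EVENT_KINDS[ev_kind[j]]
            counts[kind] += 1
            if events is not None:
                events.append(
                    MotilityEvent(int(ev_tid[j]), kind,
                                  t_offset + ev_step[j] * p.dt)
                )
        if not np.isfinite(posu).all():
            bad = np.argwhere(~np.isfinite(posu))[0]
            raise SimulationError(
                f"non-finite position for sphere {bad[0]} (twitcher "
                f"{bad[0] // SPHERES_PER_TWITCHER}) after tau interval {k}"
            )
        _record(k + 1, t_now + p.tau)

    state.pos, state.pos_unwrapped, state.vel = pos, posu, vel
    state.phase, state.anchor = phase, anchor
    state.phase_clock = np.where(
        phase == int(Phase.RETRACTION), retr_clock * p.dt,
        (t_offset + p.n_tau * p.tau) - phase_entry,
    )
    state.t = t_offset + p.n_tau * p.tau
    return counts


def simulate(
    params: SimulationParams,
    state: SystemState | None = None,
    traj_path=None,
    events_path=None,
    keep_events: bool = False,
) -> tuple[Trajectory, RunReport]:
    """Run the full twitcher simulation.

    Runs ``total_steps`` integration steps from ``state`` (or a fresh
    initial configuration), applying the motility rules on their
    schedules and sampling one frame per tau.  Identical
    ``(params, seed)`` produce identical trajectories.

    Parameters
    ----------
    params:
        Full parameter set, including ``n_twitchers`` and ``seed``.
    state:
        Optional starting state; defaults to :func:`init_configuration`.
    traj_path:
        If given, frames are streamed to this extended-XYZ style file.
    events_path:
        If given, motility events are written there as CSV.
    keep_events:
        Keep the full event list on the report (otherwise only counts).
    """
    t0 = _time.perf_counter()
    ss = np.random.SeedSequence(params.seed)
    s_init, s_motility, s_noise = ss.spawn(3)
    if state is None:
        state = init_configuration(params, np.random.default_rng(s_init))
    state.check(params)
    rng = np.random.default_rng(s_motility)
    noise_rng = np.random.default_rng(s_noise)

    traj = Trajectory.from_params(params, params.n_tau + 1)
    traj.meta.update(coverage=coverage_fraction(params.n_twitchers, params))
    events: list[MotilityEvent] = [] if (keep_events or events_path) else None

    writer = None
    if traj_path is not None:
        from .trajectory_io import TrajectoryWriter

        writer = TrajectoryWriter(traj_path)
    try:
        counts = _run(params, state, rng, traj, noise_rng=noise_rng,
                      writer=writer, events=events)
    finally:
        if writer is not None:
            writer.close()
    if events_path is not None:
        from .trajectory_io import write_events

        write_events(events_path, events)
    report = RunReport(
        seed=params.seed,
        params=params,
        frames=traj.n_frames,
        event_counts=counts,
        events=events if keep_events else [],
        wall_clock=_time.perf_counter() - t0,
        final_state=state,
    )
    return traj, report


# ----------------------------------------------------------------------
# Deterministic single-retraction experiment
# ----------------------------------------------------------------------

def retraction_arrival_time(
    params: SimulationParams | None = None,
    alpha: float = 0.0,
    max_tau: int = 100,
) -> tuple[float, str]:
    """Time for one unobstructed twitcher to finish a retraction.

    The twitcher starts straight, at mechanical equilibrium, already in
    RETRACTION with its anchor placed ``L_0`` from the head at cone
    angle ``alpha``.  Returns the elapsed time (tau units) until the
    first termination event and the event kind.  With default
    parameters the head covers ``L_0 - L_R = 2.2`` sigma at a terminal
    speed of ``k_P / (4 zeta) = 0.25``, so arrival takes roughly 10 tau.
    """
    p = (params or SimulationParams()).replace(
        n_twitchers=1, total_steps=max_tau * 100,
        # rest exits after arrival are irrelevant; keep them off so the
        # event stream contains the termination event only
        rest_exit_prob=1e-12,
    )
    b0 = equilibrium_bond_length(p)
    center = np.full(2, p.box_L / 2.0)
    state = _fresh_state(p, _rod_positions(center, 0.0, b0))
    head = state.pos[3]
    polar = np.array([1.0, 0.0])
    ca, sa = math.cos(alpha), math.sin(alpha)
    d = np.array([ca * polar[0] - sa * polar[1], sa * polar[0] + ca * polar[1]])
    state.phase[0] = int(Phase.RETRACTION)
    state.anchor[0] = np.mod(head + p.pilus_L0 * d, p.box_L)
    s_motility, s_noise = np.random.SeedSequence(p.seed).spawn(2)
    events: list[MotilityEvent] = []
    traj = Trajectory.from_params(p, p.n_tau + 1)
    _run(p, state, np.random.default_rng(s_motility), traj,
         noise_rng=np.random.default_rng(s_noise), events=events)
    term = [e for e in events if e.kind in ("ARRIVE", "SNAP", "EXHAUST")]
    if not term:
        raise SimulationError(f"retraction did not terminate within {max_tau} tau")
    return term[0].time, term[0].kind
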