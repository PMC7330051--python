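import numpy as np
import pytest

from twitchsim import _kernels
from twitchsim.engine import (
    SimulationError,
    init_configuration,
    retraction_arrival_time,
    simulate,
)
from twitchsim.forces import (
    BondOverstretchError,
    equilibrium_bond_length,
    total_energy,
)
from twitchsim.params import (
    Phase,
    SimulationParams,
    coverage_fraction,
    twitcher_count_for_coverage,
)

from conftest import make_rod_state


def _advance(state, p, nsteps, noise=None, tM_steps=None):
    """Drive the integrator kernel directly on a prepared state."""
    n = state.n_spheres
    ntw = state.n_twitchers
    f0, f1 = np.zeros((n, 2)), np.zeros((n, 2))
    clock = np.zeros(ntw, np.int64)
    head = np.empty(1, np.int64)
    nxt = np.empty(n, np.int64)
    pi = np.empty(24 * n + 64, np.int64)
    pj = np.empty(24 * n + 64, np.int64)
    ref = np.empty((n, 2))
    ev_t = np.empty(max(ntw, 1), np.int64)
    ev_k = np.empty(max(ntw, 1), np.int64)
    ev_s = np.empty(max(ntw, 1), np.int64)
    if noise is None:
        noise = np.zeros((nsteps, n, 2))
    nev, err, err_step = _kernels.advance(
        state.pos, state.pos_unwrapped, state.vel, f0, f1,
        state.phase, state.anchor, clock,
        nsteps, 0, noise,
        p.box_L, p.dt, p.sphere_mass, p.friction, p.temperature,
        p.energy_scale, p.sphere_size, p.wca_cutoff, 0.4,
        p.fene_kF, p.fene_R0, p.angle_kH, p.angle_theta0,
        p.pilus_kP, p.pilus_r0,
        p.arrive_LR, p.snap_LS,
        tM_steps if tM_steps is not None else int(p.exhaust_tM / p.dt),
        False, head, nxt, 1, pi, pj, ref,
        ev_t, ev_k, ev_s,
    )
    return nev, err, ev_t[:nev], ev_k[:nev], ev_s[:nev]


class TestLangevinIntegrator:
    def test_rest_stays_at_rest_without_noise(self):
        p = SimulationParams(total_steps=0, temperature=0.0)
        st = make_rod_state(p, [(50, 50)], [0.0], bond=equilibrium_bond_length(p))
        before = st.pos.copy()
        _advance(st, p, 100)
        assert np.abs(st.pos - before).max() < 1e-9

    def test_constant_force_matches_damped_inertia_closed_form(self):
        # A straight chain pulled at its head toward a distant on-axis
        # anchor feels a constant net force of magnitude kP.  Its centre
        # of mass obeys M v' = -zeta_tot v + F with M = 4m, zeta_tot =
        # 4 zeta, giving x(t) = (F/Z)(t - tm(1 - exp(-t/tm))), tm = m/zeta.
        p = SimulationParams(total_steps=0, temperature=0.0,
                             snap_LS=90.0, pilus_L0=40.0, exhaust_tM=1e9)
        b0 = equilibrium_bond_length(p)
        st = make_rod_state(p, [(20, 50)], [0.0], bond=b0)
        st.phase[0] = int(Phase.RETRACTION)
        st.anchor[0] = st.pos[3] + np.array([40.0, 0.0])
        com0 = st.pos_unwrapped.mean(axis=0)
        t_end = 10.0
        _advance(st, p, int(t_end / p.dt))
        com1 = st.pos_unwrapped.mean(axis=0)
        F, M, Z = p.pilus_kP, 4 * p.sphere_mass, 4 * p.friction
        tm = M / Z  # = m/zeta = 1
        expected = (F / Z) * (t_end - tm * (1.0 - np.exp(-t_end / tm)))
        assert com1[0] - com0[0] == pytest.approx(expected, abs=1e-4)
        assert com1[1] - com0[1] == pytest.approx(0.0, abs=1e-9)

    def test_free_particle_diffusion_obeys_einstein_relation(self):
        # 3 spheres (no bonds: fewer than one twitcher) far apart, kT=0.5
        kT = 0.5
        p = SimulationParams(total_steps=0, temperature=kT, box_L=1000.0)
        pos = np.array([[100.0, 100], [500, 500], [900, 200]])
        from twitchsim.kinematics import SystemState

        st = SystemState(pos.copy(), pos.copy(), np.zeros_like(pos),
                         np.zeros(0, np.int8), np.zeros(0), np.zeros((0, 2)))
        rng = np.random.default_rng(11)
        span = 400
        coms = np.empty((span + 1, 3, 2))
        coms[0] = st.pos_unwrapped
        for k in range(span):
            noise = rng.standard_normal((100, 3, 2))
            _advance(st, p, 100, noise=noise)
            coms[k + 1] = st.pos_unwrapped
        lag = 5
        d = coms[lag:] - coms[:-lag]
        msd = (d**2).sum(axis=2).mean()
        expected = 4.0 * kT / p.friction * lag
        assert msd == pytest.approx(expected, rel=0.2)

    def test_energy_conserved_at_rest_after_equilibration(self):
        p = SimulationParams(total_steps=0, temperature=0.0)
        st = make_rod_state(p, [(50, 50)], [0.4], bond=0.95,
                            perturb=0.01, rng=np.random.default_rng(7))
        _advance(st, p, 100 * 100)  # equilibrate 100 tau
        e0 = total_energy(st, p) + 0.5 * (st.vel**2).sum()
        drift = []
        for _ in range(50):
            _advance(st, p, 100)
            e1 = total_energy(st, p) + 0.5 * (st.vel**2).sum()
            drift.append(abs(e1 - e0))
            e0 = e1
        assert max(drift) < 1e-6


class TestRetractionTermination:
    def _retracting(self, p, anchor_offset):
        st = make_rod_state(p, [(50, 50)], [0.0],
                            bond=equilibrium_bond_length(p))
        st.phase[0] = int(Phase.RETRACTION)
        st.anchor[0] = np.mod(st.pos[3] + anchor_offset, p.box_L)
        return st

    def test_arrive_below_LR(self):
        p = SimulationParams(total_steps=0, temperature=0.0)
        st = self._retracting(p, np.array([0.15, 0.0]))
        nev, err, tid, kind, step = _advance(st, p, 1)
        assert nev == 1 and kind[0] == _kernels.EV_ARRIVE
        assert st.phase[0] == int(Phase.REST)
        assert np.all(np.isnan(st.anchor[0]))

    def test_snap_beyond_LS(self):
        p = SimulationParams(total_steps=0, temperature=0.0)
        st = self._retracting(p, np.array([3.05, 0.0]))
        nev, err, tid, kind, step = _advance(st, p, 1)
        assert nev == 1 and kind[0] == _kernels.EV_SNAP

    def test_exhaust_at_tM(self):
        p = SimulationParams(total_steps=0, temperature=0.0)
        st = self._retracting(p, np.array([0.0, 2.4]))
        # hold the twitcher overlong by making tM tiny (3 steps)
        nev, err, tid, kind, step = _advance(st, p, 5, tM_steps=3)
        assert nev == 1 and kind[0] == _kernels.EV_EXHAUST
        assert step[0] == 3


class TestInitialConfiguration:
    def test_random_insertion_is_overlap_free(self):
        p = SimulationParams(total_steps=0, n_twitchers=300)
        st = init_configuration(p, np.random.default_rng(0))
        pos = st.pos
        n = pos.shape[0]
        # no sphere pair closer than the insertion energy cap radius
        from scipy.spatial import cKDTree

        from twitchsim.engine import _overlap_radius

        tree = cKDTree(pos, boxsize=p.box_L)
        pairs = tree.query_pairs(_overlap_radius(p))
        assert pairs == set()
        assert st.n_twitchers == 300
        assert np.all(st.phase == int(Phase.REST))

    def test_lattice_mode_fits_all_spheres(self):
        p = SimulationParams(total_steps=0, n_twitchers=300, box_L=40.0)
        assert coverage_fraction(300, p) > 0.3  # lattice path
        st = init_configuration(p, np.random.default_rng(1))
        assert st.n_spheres == 1200
        assert np.all((st.pos >= 0) & (st.pos < p.box_L))
        # bonds near mechanical equilibrium after the warm-up
        b = np.linalg.norm(
            np.diff(st.pos_unwrapped.reshape(-1, 4, 2), axis=1), axis=2
        )
        assert abs(np.median(b) - equilibrium_bond_length(p)) < 0.02

    def test_single_twitcher_coverage(self):
        p = SimulationParams(total_steps=0, n_twitchers=1)
        init_configuration(p, np.random.default_rng(0))
        assert coverage_fraction(1, p) == pytest.approx(3.7854e-4, rel=1e-4)

    def test_excessive_coverage_rejected(self):
        n = twitcher_count_for_coverage(0.85)
        p = SimulationParams(total_steps=0, n_twitchers=n)
        with pytest.raises(ValueError):
            init_configuration(p, np.random.default_rng(0))


class TestSimulate:
    def test_zero_steps_yields_initial_frame_only(self):
        p = SimulationParams(n_twitchers=2, total_steps=0, seed=1)
        traj, rep = simulate(p)
        assert traj.n_frames == 1
        assert rep.frames == 1

    def test_identical_seed_reproduces_trajectory(self):
        p = SimulationParams(n_twitchers=4, total_steps=300 * 100, seed=42)
        t1, _ = simulate(p)
        t2, _ = simulate(p)
        assert np.array_equal(t1.com, t2.com)
        assert np.array_equal(t1.phase, t2.phase)

    def test_different_seed_changes_trajectory(self):
        p = SimulationParams(n_twitchers=4, total_steps=300 * 100, seed=42)
        t1, _ = simulate(p)
        t2, _ = simulate(p.replace(seed=43))
        assert not np.array_equal(t1.com, t2.com)

    def test_frame_cadence_and_count(self):
        p = SimulationParams(n_twitchers=1, total_steps=250 * 100, seed=0)
        traj, _ = simulate(p)
        assert traj.n_frames == 251
        assert np.allclose(np.diff(traj.times), 1.0)

    def test_bonds_never_overstretch_in_default_run(self):
        p = SimulationParams(n_twitchers=8, box_L=30.0,
                             total_steps=2000 * 100, seed=6)
        traj, rep = simulate(p)
        st = rep.final_state
        b = np.linalg.norm(
            np.diff(st.pos_unwrapped.reshape(-1, 4, 2), axis=1), axis=2
        )
        assert b.max() < p.fene_R0


class TestUnobstructedRetraction:
    def test_arrival_takes_roughly_ten_tau(self):
        t, kind = retraction_arrival_time()
        assert kind == "ARRIVE"
        assert t == pytest.approx(10.0, abs=2.0)

    def test_arrival_from_cone_edge_is_similar(self):
        t, kind = retraction_arrival_time(alpha=np.pi / 4)
        assert kind == "ARRIVE"
        assert t == pytest.approx(10.0, abs=3.0)
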