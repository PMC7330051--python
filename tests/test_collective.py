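import numpy as np
import pytest

from twitchsim import synthetic as syn
from twitchsim.collective import (
    local_coverage,
    local_coverage_distribution,
    number_fluctuations,
    pair_correlation,
    raft_length,
    speed_decomposition,
)
from twitchsim.observables import CorrelationCurve
from twitchsim.params import Phase, twitcher_area
from twitchsim.trajectory import Trajectory


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(202)


def _traj(com, polar=None, phase=None, box_L=100.0):
    return Trajectory(
        times=np.arange(com.shape[0], dtype=float), com=com, polar=polar,
        phase=phase, box_L=box_L, a_twitch=twitcher_area(),
    )


class TestSpeedDecomposition:
    def test_frozen_resters_have_zero_speeds(self):
        com = np.tile(np.array([[10.0, 10.0], [20.0, 20.0]]), (50, 1, 1))
        phase = np.zeros((50, 2), dtype=np.int8)
        s = speed_decomposition(_traj(com, phase=phase), warmup_frac=0.0)
        assert s.v_mean == 0.0 and s.v_passive == 0.0
        assert s.f_active == 0.0

    def test_weighted_identity_holds_exactly(self, rng):
        f, n = 400, 30
        com = np.cumsum(rng.normal(0, 0.3, (f, n, 2)), axis=0) + 50
        phase = rng.integers(0, 3, size=(f, n)).astype(np.int8)
        s = speed_decomposition(_traj(com, phase=phase), warmup_frac=0.0)
        lhs = s.f_active * s.v_active + (1 - s.f_active) * s.v_passive
        assert s.v_mean == pytest.approx(lhs, rel=1e-12)
        assert sum(s.phase_occupancy.values()) == pytest.approx(1.0)

    def test_solitary_active_speed_matches_drag_balance(self):
        # head force kP=1 dragging 4 spheres of friction zeta=1 gives a
        # terminal speed 0.25; averaged over the ~9.8-tau retraction
        # (acceleration + arrival) the mean active speed is ~2.2/9.8
        from twitchsim.engine import simulate
        from twitchsim.params import SimulationParams

        p = SimulationParams(n_twitchers=1, total_steps=8000 * 100, seed=14)
        traj, _ = simulate(p)
        s = speed_decomposition(traj, warmup_frac=0.0)
        assert s.v_active == pytest.approx(2.2 / 9.8, rel=0.10)
        assert s.v_active > 3 * s.v_passive

    def test_active_twitchers_attributed_by_interval_start(self):
        # one twitcher retracting in the first interval only
        com = np.array([[[0.0, 0.0]], [[1.0, 0.0]], [[1.0, 0.0]]]) + 50
        phase = np.array([[int(Phase.RETRACTION)], [int(Phase.REST)],
                          [int(Phase.REST)]], dtype=np.int8)
        s = speed_decomposition(_traj(com, phase=phase), warmup_frac=0.0)
        assert s.v_active == pytest.approx(1.0)
        assert s.v_passive == pytest.approx(0.0)


class TestPairCorrelation:
    def test_identical_movers_fully_correlated(self):
        f, n = 20, 12
        base = np.linspace(5, 95, n)
        com = np.zeros((f, n, 2))
        com[..., 0] = base + 0.5 * np.arange(f)[:, None]
        com[..., 1] = 50.0
        tr = _traj(com)
        g = pair_correlation(tr, which="v", warmup_frac=0.0)
        vals = g.value[g.counts > 0]
        assert np.allclose(vals, 1.0)

    def test_antiparallel_polar_pair(self):
        com = np.zeros((4, 2, 2)) + 50
        com[:, 1, 0] += 3.0
        polar = np.zeros((4, 2, 2))
        polar[:, 0] = (1.0, 0.0)
        polar[:, 1] = (-1.0, 0.0)
        tr = _traj(com, polar=polar)
        gp = pair_correlation(tr, which="p", warmup_frac=0.0)
        assert np.nanmin(gp.value[gp.counts > 0]) == pytest.approx(-1.0)
        # headless director: anti-parallel pairs are perfectly aligned
        gn = pair_correlation(tr, which="n", warmup_frac=0.0)
        assert np.nanmax(gn.value[gn.counts > 0]) == pytest.approx(1.0)

    def test_isotropic_directors_average_to_zero(self, rng):
        f, n = 200, 80
        com = rng.uniform(0, 100, (f, n, 2))
        th = rng.uniform(0, 2 * np.pi, (f, n))
        polar = np.stack([np.cos(th), np.sin(th)], axis=-1)
        tr = _traj(com, polar=polar)
        g = pair_correlation(tr, which="n", warmup_frac=0.0)
        big = g.counts > 1000
        assert big.any()
        assert np.abs(g.value[big]).max() < 0.08

    def test_nematic_invariant_under_director_sign_flip(self, rng):
        f, n = 10, 20
        com = rng.uniform(0, 100, (f, n, 2))
        th = rng.uniform(0, 2 * np.pi, (f, n))
        polar = np.stack([np.cos(th), np.sin(th)], axis=-1)
        flip = rng.random((f, n)) < 0.5
        flipped = polar.copy()
        flipped[flip] *= -1
        g1 = pair_correlation(_traj(com, polar=polar), which="n",
                              warmup_frac=0.0)
        g2 = pair_correlation(_traj(com, polar=flipped), which="n",
                              warmup_frac=0.0)
        assert np.allclose(g1.value[g1.counts > 0], g2.value[g2.counts > 0])

    def test_values_bounded(self, rng):
        f, n = 30, 40
        com = rng.uniform(0, 100, (f, n, 2))
        th = rng.uniform(0, 2 * np.pi, (f, n))
        polar = np.stack([np.cos(th), np.sin(th)], axis=-1)
        for which in ("p", "n"):
            g = pair_correlation(_traj(com, polar=polar), which=which,
                                 warmup_frac=0.0)
            ok = g.counts > 0
            assert np.all(g.value[ok] <= 1 + 1e-12)
            assert np.all(g.value[ok] >= -1 - 1e-12)

    def test_raft_length_recovers_exact_tail(self):
        x = np.arange(0.1, 20.0, 0.2)
        c = CorrelationCurve(x, 0.5 * np.exp(-x / 3.0),
                             np.full(x.size, 10, dtype=np.int64))
        assert raft_length(c, (5, 15)) == pytest.approx(3.0, rel=1e-6)


class TestLocalCoverage:
    def test_occupancies_sum_to_population(self, rng):
        tr = syn.uniform_field(n_points=123, n_frames=40, rng=rng)
        field = local_coverage(tr, n_grid=10)
        assert np.all(field.counts.sum(axis=1) == 123)

    def test_distribution_mean_equals_global_coverage(self, rng):
        tr = syn.uniform_field(n_points=200, n_frames=50, rng=rng)
        d = local_coverage_distribution(tr, warmup_frac=0.0)
        assert d.mean_phi == pytest.approx(tr.coverage, rel=1e-12)
        assert d.prob.sum() == pytest.approx(1.0)

    def test_all_mass_in_one_subdomain(self):
        n, f = 40, 10
        com = np.full((f, n, 2), 3.0)  # everyone in the corner cell
        tr = _traj(com)
        d = local_coverage_distribution(tr, warmup_frac=0.0)
        occupied = d.centers[d.prob > 0]
        q = tr.a_twitch / 10.0**2
        assert set(np.round(occupied, 6)) == {0.0, round(n * q, 6)}
        assert d.prob[np.argmin(np.abs(d.centers))] == pytest.approx(0.99)

    def test_uniform_placement_is_unimodal_near_global(self, rng):
        tr = syn.uniform_field(n_points=400, n_frames=200, rng=rng)
        d = local_coverage_distribution(tr, warmup_frac=0.0)
        mode = d.centers[np.argmax(d.prob)]
        assert mode == pytest.approx(tr.coverage, abs=0.05)


class TestNumberFluctuations:
    def test_poisson_placement_obeys_central_limit(self, rng):
        tr = syn.uniform_field(n_points=400, n_frames=300, rng=rng)
        f = number_fluctuations(tr, warmup_frac=0.0)
        assert f.mu == pytest.approx(0.5, abs=0.05)

    def test_common_density_factor_gives_giant_fluctuations(self, rng):
        tr = syn.clustered_field(n_points=4000, n_frames=200, rng=rng)
        f = number_fluctuations(tr, warmup_frac=0.0)
        assert f.mu > 0.85

    def test_empty_system_has_zero_fluctuations(self):
        tr = _traj(np.zeros((20, 0, 2)))
        f = number_fluctuations(tr, warmup_frac=0.0)
        assert np.all(f.std_occupancy == 0)
        assert np.isnan(f.mu)

    def test_too_few_window_sizes_rejected(self, rng):
        tr = syn.uniform_field(n_points=50, n_frames=10, rng=rng)
        with pytest.raises(ValueError):
            number_fluctuations(tr, window_sizes=[10, 20], warmup_frac=0.0)

    def test_window_must_divide_box(self, rng):
        tr = syn.uniform_field(n_points=50, n_frames=10, rng=rng)
        with pytest.raises(ValueError):
            number_fluctuations(tr, window_sizes=[7, 10, 20], warmup_frac=0.0)
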