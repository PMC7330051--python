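import math

import numpy as np
import pytest

from twitchsim import synthetic as syn
from twitchsim.observables import (
    CorrelationCurve,
    diffusivity,
    fit_beta,
    fit_decorrelation_length,
    iac,
    msd,
    msv,
    ngp,
    relative_diffusivity,
    van_hove,
)


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(101)


class TestMSD:
    def test_ballistic_is_exactly_quadratic(self):
        v = 0.5
        tr = syn.ballistic(speed=v, n_frames=64)
        c = msd(tr)
        assert np.allclose(c.msd[1:], (v * c.lags[1:]) ** 2, rtol=1e-12)
        assert c.msd[0] == 0.0
        assert fit_beta(c, (1, 10)) == pytest.approx(2.0, abs=1e-9)

    def test_two_frame_displacement(self):
        tr = syn.ballistic(speed=5.0, n_frames=2, direction=(0.6, 0.8))
        c = msd(tr, lags=[1])
        assert c.msd[1] == pytest.approx(25.0)

    def test_brownian_recovers_diffusivity(self, rng):
        d0 = 0.7
        tr = syn.brownian(d0, n_frames=20000, n_walkers=40, rng=rng)
        c = msd(tr)
        assert fit_beta(c, (1, 100)) == pytest.approx(1.0, abs=0.05)
        # fit the linear regime well inside the span, where the
        # time-origin average has many independent windows
        c2 = msd(tr, lags=np.arange(100, 2001, 100))
        assert diffusivity(c2, t_min=100) == pytest.approx(d0, rel=0.05)

    def test_quartic_moment_bounded_below_by_squared_msd(self, rng):
        tr = syn.brownian(1.0, n_frames=3000, n_walkers=4, rng=rng)
        c = msd(tr)
        assert np.all(c.mqd[1:] >= c.msd[1:] ** 2 * (1 - 1e-12))

    def test_lag_beyond_span_rejected(self):
        tr = syn.ballistic(n_frames=16)
        with pytest.raises(ValueError):
            msd(tr, lags=[50])


class TestNGP:
    def test_gaussian_steps_have_zero_ngp(self, rng):
        tr = syn.brownian(1.0, n_frames=2, n_walkers=200_000, rng=rng)
        a = ngp(msd(tr, lags=[1]))
        assert a.value[0] == pytest.approx(0.0, abs=0.02)

    def test_shell_steps_reach_lower_bound(self, rng):
        # fixed-length steps: <r^4> = <r^2>^2, alpha_2 = -2/(d+2) = -1/2
        tr = syn.shell_steps(rng=rng)
        a = ngp(msd(tr, lags=[1]))
        assert a.value[0] == pytest.approx(-0.5, abs=1e-9)

    def test_zero_gaussian_mixture_is_leptokurtic(self, rng):
        # 50/50 frozen/Gaussian: <r^2> = sigma^2, <r^4> = 4 sigma^4 -> 1
        tr = syn.zero_gaussian_mixture(rng=rng)
        a = ngp(msd(tr, lags=[1]))
        assert a.value[0] == pytest.approx(1.0, abs=0.05)

    def test_ngp_never_below_moment_bound(self, rng):
        tr = syn.persistent_walk(n_frames=2000, n_walkers=4, rng=rng)
        a = ngp(msd(tr))
        assert np.all(a.value >= -0.5 - 1e-9)


class TestVanHove:
    def test_normalization(self, rng):
        tr = syn.brownian(1.0, n_frames=2000, n_walkers=2, rng=rng)
        vh = van_hove(tr, 10)
        assert np.sum(vh.density * np.diff(vh.edges)) == pytest.approx(1.0)

    def test_ballistic_peaks(self):
        v, t = 0.8, 10
        tr = syn.ballistic(speed=v, n_frames=64, direction=(1, 0))
        vh = van_hove(tr, t, bins=np.linspace(-10, 10, 201))
        # pooling both axes: peaks at +vt (x axis) and 0 (y axis)
        peaks = vh.centers[vh.density > 0]
        assert np.any(np.abs(peaks - v * t) < 0.1)
        assert np.any(np.abs(peaks) < 0.1)

    def test_diffusive_collapse(self, rng):
        tr = syn.brownian(1.0, n_frames=60000, n_walkers=4, rng=rng)
        v1 = van_hove(tr, 100, bins=81)
        v2 = van_hove(tr, 1000, bins=81)
        x1, g1 = v1.collapse()
        x2, g2 = v2.collapse()
        g2i = np.interp(x1, x2, g2)
        # collapsed diffusive curves overlap to within sampling noise
        assert np.max(np.abs(g1 - g2i)) < 0.05 * g1.max() + 0.01

    def test_gaussian_reference_matches_brownian(self, rng):
        tr = syn.brownian(1.0, n_frames=40000, n_walkers=2, rng=rng)
        vh = van_hove(tr, 50, bins=61)
        ref = vh.gaussian_reference()
        sel = vh.density > 0.01 * vh.density.max()
        assert np.max(np.abs(vh.density - ref)[sel]) < 0.06 * vh.density.max()

    def test_zero_lag_rejected(self):
        tr = syn.ballistic(n_frames=16)
        with pytest.raises(ValueError):
            van_hove(tr, 0.0)


class TestVelocityScales:
    def test_ballistic_msv_is_speed_squared(self):
        tr = syn.ballistic(speed=0.3, n_frames=32)
        assert msv(msd(tr)) == pytest.approx(0.09)

    def test_relative_diffusivity_is_dimensionless(self):
        # rescaling time units consistently leaves D unchanged
        d, v2, tau = 0.37, 1.4, 1.0
        s = 10.0  # time rescale factor
        assert relative_diffusivity(d, v2, tau) == pytest.approx(
            relative_diffusivity(d / s, v2 / s**2, tau * s)
        )

    def test_nonpositive_msv_rejected(self):
        with pytest.raises(ValueError):
            relative_diffusivity(1.0, 0.0)

    def test_diffusivity_requires_span(self):
        tr = syn.ballistic(n_frames=64)
        with pytest.raises(ValueError):
            diffusivity(msd(tr), t_min=1e4)


class TestIAC:
    def test_straight_mover_fully_correlated(self):
        tr = syn.ballistic(speed=1.0, n_frames=256)
        c = iac(tr, bin_width=1.0, max_dr=100.0)
        assert np.allclose(c.value[c.counts > 0], 1.0)

    def test_iid_directions_decorrelate_immediately(self, rng):
        tr = syn.shell_steps(step_length=1.0, n_frames=2000, n_walkers=4,
                             rng=rng)
        c = iac(tr, bin_width=1.0, max_dr=30.0)
        beyond = c.value[(c.x >= 2) & (c.counts > 100)]
        assert np.abs(beyond).max() < 0.1

    def test_persistent_walk_decay_length(self, rng):
        speed, d_rot = 1.0, 0.05
        tr = syn.persistent_walk(speed=speed, d_rot=d_rot, n_frames=6000,
                                 n_walkers=24, rng=rng)
        c = iac(tr, bin_width=1.0, max_dr=70.0)
        lam = fit_decorrelation_length(c, (3, 50))
        assert lam == pytest.approx(speed / d_rot, rel=0.05)

    def test_net_displacement_variant(self, rng):
        tr = syn.ballistic(speed=1.0, n_frames=128)
        c = iac(tr, bin_width=1.0, max_dr=50.0, abscissa="net")
        assert np.allclose(c.value[c.counts > 0], 1.0)
        with pytest.raises(ValueError):
            iac(tr, abscissa="bogus")


class TestDecorrelationFit:
    def test_exact_exponential(self):
        x = np.arange(1.0, 51.0)
        c = CorrelationCurve(x, np.exp(-x / 5.0), np.ones_like(x, dtype=np.int64))
        assert fit_decorrelation_length(c, (1, 50)) == pytest.approx(5.0)

    def test_prefactor_invariance(self):
        x = np.arange(1.0, 51.0)
        for a in (0.3, 1.0, 7.0):
            c = CorrelationCurve(x, a * np.exp(-x / 8.0),
                                 np.ones_like(x, dtype=np.int64))
            assert fit_decorrelation_length(c, (1, 50)) == pytest.approx(8.0)

    def test_noisy_tail_recovery(self, rng):
        x = np.arange(1.0, 51.0)
        y = np.exp(-x / 12.0) * (1 + 0.01 * rng.standard_normal(50))
        c = CorrelationCurve(x, y, np.ones_like(x, dtype=np.int64))
        assert fit_decorrelation_length(c, (1, 50)) == pytest.approx(12.0, rel=0.05)

    def test_nonpositive_values_shrink_range_with_warning(self):
        x = np.arange(1.0, 21.0)
        y = np.exp(-x / 4.0)
        y[10:] = -1e-3
        c = CorrelationCurve(x, y, np.ones_like(x, dtype=np.int64))
        with pytest.warns(UserWarning):
            lam = fit_decorrelation_length(c, (1, 20))
        assert lam == pytest.approx(4.0, rel=1e-6)

    def test_empty_range_rejected(self):
        c = CorrelationCurve(np.array([1.0]), np.array([0.5]),
                             np.array([1], dtype=np.int64))
        with pytest.raises(ValueError):
            fit_decorrelation_length(c, (10, 20))
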