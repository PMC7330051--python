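"""Single-trajectory displacement statistics.

Implements the displacement-statistics suite for twitcher trajectories:
the mean squared displacement over all time origins,

    MSD(t) = < |x(0) - x(t)|^2 >,

its log-log scaling exponent beta, the non-Gaussian parameter

    alpha_2(t) = (d / (d+2)) <Dr^4> / <Dr^2>^2 - 1     (d = 2),

van Hove displacement distributions G(Dx, t), the short-time mean
squared velocity V^2 = MSD(tau)/tau^2, the long-time diffusion
coefficient and the dimensionless relative diffusivity D = Dcal/(tau V^2),
and the individual auto-correlation (IAC) of the direction of motion
along each twitcher's own path, with exponential decorrelation-length
fits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .trajectory import Trajectory

__all__ = [
    "MSDCurve",
    "CorrelationCurve",
    "VanHove",
    "log_lags",
    "msd",
    "fit_beta",
    "ngp",
    "van_hove",
    "msv",
    "diffusivity",
    "relative_diffusivity",
    "iac",
    "fit_decorrelation_length",
]


@dataclass
class MSDCurve:
    """Binned second and fourth displacement moments vs lag time."""

    lags: np.ndarray      # lag times (tau units), includes 0
    msd: np.ndarray       # <Dr^2>
    mqd: np.ndarray       # <Dr^4>
    counts: np.ndarray    # origin x twitcher samples per lag
    meta: dict = field(default_factory=dict)


@dataclass
class CorrelationCurve:
    """A binned statistic vs an abscissa (lag, path length or separation)."""

    x: np.ndarray
    value: np.ndarray
    counts: np.ndarray
    meta: dict = field(default_factory=dict)


def log_lags(n_frames: int, per_decade: int = 20, max_lag: int | None = None) -> np.ndarray:
    """Approximately log-spaced integer frame lags up to half the span."""
    if max_lag is None:
        max_lag = (n_frames - 1) // 2
    max_lag = max(int(max_lag), 1)
    raw = np.logspace(0, math.log10(max_lag), int(per_decade * math.log10(max_lag)) + 1)
    lags = np.unique(np.round(raw).astype(np.int64))
    return lags[(lags >= 1) & (lags <= max_lag)]


def msd(traj: Trajectory, lags: np.ndarray | None = None) -> MSDCurve:
    """Mean squared (and quartic) displacement over all time origins.

    Averages |x(0) - x(t)|^2 and |x(0) - x(t)|^4 over every time origin
    and every twitcher, at a log-spaced subset of frame lags.
    """
    com = traj.com
    n_frames = traj.n_frames
    if n_frames < 2:
        raise ValueError("trajectory too short for displacement statistics")
    if lags is None:
        lag_frames = log_lags(n_frames)
    else:
        lag_frames = np.unique(
            np.round(np.asarray(lags) / traj.frame_dt).astype(np.int64)
        )
        lag_frames = lag_frames[lag_frames >= 1]
    if lag_frames.size == 0 or lag_frames.max() > n_frames - 1:
        raise ValueError("requested lag exceeds the trajectory span")
    out_l = np.empty(lag_frames.size + 1)
    out_2 = np.empty(lag_frames.size + 1)
    out_4 = np.empty(lag_frames.size + 1)
    out_c = np.empty(lag_frames.size + 1, dtype=np.int64)
    out_l[0], out_2[0], out_4[0] = 0.0, 0.0, 0.0
    out_c[0] = n_frames * traj.n_twitchers
    for i, l in enumerate(lag_frames):
        d = com[l:] - com[:-l]
        r2 = d[..., 0] ** 2 + d[..., 1] ** 2
        out_l[i + 1] = l * traj.frame_dt
        out_2[i + 1] = r2.mean()
        out_4[i + 1] = (r2 * r2).mean()
        out_c[i + 1] = r2.size
    return MSDCurve(out_l, out_2, out_4, out_c,
                    meta={"n_twitchers": traj.n_twitchers, "span": traj.span})


def fit_beta(curve: MSDCurve, window: tuple[float, float] = (1.0, 10.0)) -> float:
    """Least-squares log-log slope of the MSD over a lag window."""
    lo, hi = window
    sel = (curve.lags >= lo) & (curve.lags <= hi)
    if np.count_nonzero(sel) < 4:
        raise ValueError(f"fewer than 4 MSD points in window [{lo}, {hi}]")
    y = curve.msd[sel]
    if np.any(y <= 0):
        raise ValueError("non-positive MSD values in fit window")
    return float(np.polyfit(np.log(curve.lags[sel]), np.log(y), 1)[0])


def ngp(curve: MSDCurve, d: int = 2) -> CorrelationCurve:
    """Non-Gaussian parameter alpha_2(t) from an MSD curve.

    Zero for Gaussian displacements; bounded below by -2/(d+2).  Lags
    with zero MSD (including lag 0) are excluded.
    """
    ok = curve.msd > 0
    a2 = (d / (d + 2.0)) * curve.mqd[ok] / curve.msd[ok] ** 2 - 1.0
    return CorrelationCurve(curve.lags[ok], a2, curve.counts[ok], meta={"d": d})


@dataclass
class VanHove:
    """1D displacement distribution G(Dx, t), both axes pooled."""

    t: float
    edges: np.ndarray
    density: np.ndarray
    n_samples: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def gaussian_reference(self) -> np.ndarray:
        """Normal density with the same standard deviation, on centers."""
        var = np.sum(self.density * np.diff(self.edges) * self.centers**2)
        return np.exp(-self.centers**2 / (2 * var)) / math.sqrt(2 * math.pi * var)

    def collapse(self) -> tuple[np.ndarray, np.ndarray]:
        """Diffusive collapse transform (Dx t^-1/2, G t^1/2)."""
        s = math.sqrt(self.t)
        return self.centers / s, self.density * s


def van_hove(traj: Trajectory, t: float, bins=101, x_range=None) -> VanHove:
    """Distribution of 1D displacements at lag ``t``.

    Pools both Cartesian components of the per-twitcher displacement
    over all time origins into one normalized histogram.
    """
    l = int(round(t / traj.frame_dt))
    if l < 1 or l > traj.n_frames - 1:
        raise ValueError(f"lag {t} outside the trajectory span")
    dx = (traj.com[l:] - traj.com[:-l]).ravel()
    if dx.size == 0:
        raise ValueError("no displacement samples at this lag")
    density, edges = np.histogram(dx, bins=bins, range=x_range, density=True)
    return VanHove(t=l * traj.frame_dt, edges=edges, density=density,
                   n_samples=dx.size)


def msv(curve: MSDCurve, tau: float = 1.0) -> float:
    """Short-time mean squared velocity V^2 = MSD(tau) / tau^2."""
    i = np.argmin(np.abs(curve.lags - tau))
    if not math.isclose(curve.lags[i], tau, rel_tol=1e-6):
        raise ValueError("MSD curve has no point at lag tau")
    return float(curve.msd[i] / tau**2)


def diffusivity(curve: MSDCurve, t_min: float = 1e4, d: int = 2) -> float:
    """Long-time diffusion coefficient from MSD(t) ~ 2 d Dcal t.

    Fits a straight line to MSD vs t over lags beyond ``t_min`` and
    returns slope / (2 d).
    """
    sel = curve.lags >= t_min
    if np.count_nonzero(sel) < 2:
        raise ValueError(f"MSD does not span lags beyond t_min={t_min}")
    slope = np.polyfit(curve.lags[sel], curve.msd[sel], 1)[0]
    return float(slope / (2 * d))


def relative_diffusivity(dcal: float, v2: float, tau: float = 1.0) -> float:
    """Dimensionless relative diffusivity D = Dcal / (tau V^2)."""
    if v2 <= 0:
        raise ValueError("mean squared velocity must be positive")
    return dcal / (tau * v2)


# ----------------------------------------------------------------------
# Individual auto-correlation along the path
# ----------------------------------------------------------------------

@njit(cache=True)
def _iac_path(dirs, ok, steplen, bw, nbins, stride, sums, counts):
    n_int, n_tw = ok.shape
    for g in range(n_tw):
        for o in range(0, n_int, stride):
            if not ok[o, g]:
                continue
            v0x = dirs[o, g, 0]
            v0y = dirs[o, g, 1]
            s = 0.0
            nxt = 1
            for t in range(o + 1, n_int):
                s += steplen[t - 1, g]
                while nxt <= nbins and nxt * bw <= s:
                    if ok[t, g]:
                        sums[nxt - 1] += v0x * dirs[t, g, 0] + v0y * dirs[t, g, 1]
                        counts[nxt - 1] += 1
                    nxt += 1
                if nxt > nbins:
                    break


@njit(cache=True)
def _iac_net(com, dirs, ok, steplen, bw, nbins, stride, sums, counts):
    n_int, n_tw = ok.shape
    for g in range(n_tw):
        for o in range(0, n_int, stride):
            if not ok[o, g]:
                continue
            v0x = dirs[o, g, 0]
            v0y = dirs[o, g, 1]
            path = 0.0
            for t in range(o + 1, n_int):
                path += steplen[t - 1, g]
                if path > 4.0 * nbins * bw:
                    break
                if not ok[t, g]:
                    continue
                dx = com[t, g, 0] - com[o, g, 0]
                dy = com[t, g, 1] - com[o, g, 1]
                b = int(np.sqrt(dx * dx + dy * dy) / bw)
                if b < nbins:
                    sums[b] += v0x * dirs[t, g, 0] + v0y * dirs[t, g, 1]
                    counts[b] += 1


def iac(
    traj: Trajectory,
    bin_width: float = 1.0,
    max_dr: float = 100.0,
    origin_stride: int = 1,
    abscissa: str = "path",
) -> CorrelationCurve:
    """Individual auto-correlation of the direction of motion.

    rho(Dr) = < v_hat(0) . v_hat(Dr) > averaged over time origins and
    twitchers, where Dr is by default the cumulative path length of the
    centre of mass sampled at tau resolution ("distance travelled"); the
    correlation at each Dr bin is taken at the first sample whose
    cumulative path reaches that Dr.  With ``abscissa="net"`` the net
    displacement |x(t) - x(0)| is binned instead.  Zero-speed samples
    carry no direction and are skipped.
    """
    if abscissa not in ("path", "net"):
        raise ValueError("abscissa must be 'path' or 'net'")
    dirs, ok = traj.directions()
    steplen = traj.speeds() * traj.frame_dt
    nbins = int(round(max_dr / bin_width))
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=np.int64)
    if abscissa == "path":
        _iac_path(dirs, ok, steplen, bin_width, nbins, origin_stride,
                  sums, counts)
        x = bin_width * np.arange(1, nbins + 1)
    else:
        _iac_net(traj.com, dirs, ok, steplen, bin_width, nbins,
                 origin_stride, sums, counts)
        x = bin_width * (np.arange(nbins) + 0.5)
    value = np.full(nbins, np.nan)
    nz = counts > 0
    value[nz] = sums[nz] / counts[nz]
    return CorrelationCurve(x, value, counts,
                            meta={"abscissa": abscissa, "bin_width": bin_width})


def fit_decorrelation_length(
    curve: CorrelationCurve, fit_range: tuple[float, float] = (20.0, 80.0)
) -> float:
    """Exponential decay length from the tail of a correlation curve.

    Least-squares fit of log(value) vs abscissa over ``fit_range``;
    returns -1/slope.  Invariant to the prefactor.  Non-positive values
    inside the range shrink it (with a warning) to the leading positive
    stretch.
    """
    lo, hi = fit_range
    sel = (curve.x >= lo) & (curve.x <= hi) & (curve.counts > 0)
    x = curve.x[sel]
    y = curve.value[sel]
    if y.size and np.any(y <= 0):
        n_pos = int(np.argmax(y <= 0))  # first non-positive value
        warnings.warn(
            "non-positive correlation values inside the fit range; "
            f"shrinking to the first {n_pos} points"
        )
        x, y = x[:n_pos], y[:n_pos]
    if y.size < 2:
        raise ValueError("fewer than 2 usable points in the fit range")
    slope = np.polyfit(x, np.log(y), 1)[0]
    if slope >= 0:
        return math.inf
    return float(-1.0 / slope)
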