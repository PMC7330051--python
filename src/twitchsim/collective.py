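"""Ensemble statistics: speeds by phase, pair correlations, coexistence
and number-fluctuation scaling.

The pair auto-correlation (PAC) compares twitchers to their neighbours
at the same instant as a function of pair separation: the direction of
motion g_v(Dr) = <v_g . v_e>, the polar orientation g_p(Dr) = <p_g . p_e>,
and the nematic director, for which the standard 2D headless correlator
<cos 2 theta_ge> is the default.  Local structure is quantified by the
distribution P(phi'; phi) of per-sub-domain coverage over a 10 x 10
partition of the box, and by the scaling of window occupancy
fluctuations DN ~ <N>^mu across window sizes: mu = 1/2 for uncorrelated
(central-limit) placements, mu -> 1 for giant number fluctuations of
ordered active phases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .observables import CorrelationCurve, fit_decorrelation_length
from .params import Phase
from .trajectory import Trajectory

__all__ = [
    "SpeedDecomposition",
    "speed_decomposition",
    "pair_correlation",
    "raft_length",
    "CoverageField",
    "local_coverage",
    "CoverageDistribution",
    "local_coverage_distribution",
    "FluctuationScaling",
    "number_fluctuations",
]


# ----------------------------------------------------------------------
# Speed decomposition by motility phase
# ----------------------------------------------------------------------

@dataclass
class SpeedDecomposition:
    """Mean speeds split by motility phase.

    ``v_mean = f_active * v_active + (1 - f_active) * v_passive`` holds
    exactly by construction (weighted average identity).
    """

    v_mean: float
    v_active: float
    v_passive: float
    f_active: float
    phase_occupancy: dict


def speed_decomposition(traj: Trajectory, warmup_frac: float = 0.1) -> SpeedDecomposition:
    """Mean speed of all twitchers and its retraction/rest split.

    Each tau interval is attributed to the phase the twitcher was in at
    the interval start; means run over all twitchers and post-warm-up
    frames.
    """
    if traj.phase is None:
        raise ValueError("trajectory carries no phase data")
    tr = traj.steady_slice(warmup_frac)
    if tr.n_frames < 2:
        raise ValueError("trajectory too short")
    v = tr.speeds()
    ph = tr.phase[:-1]
    active = ph == int(Phase.RETRACTION)
    n = v.size
    f_a = float(np.count_nonzero(active)) / n if n else 0.0
    v_a = float(v[active].mean()) if active.any() else 0.0
    v_r = float(v[~active].mean()) if (~active).any() else 0.0
    occ = {
        p.name: float(np.count_nonzero(ph == int(p))) / n for p in Phase
    }
    return SpeedDecomposition(
        v_mean=float(v.mean()) if n else 0.0,
        v_active=v_a,
        v_passive=v_r,
        f_active=f_a,
        phase_occupancy=occ,
    )


# ----------------------------------------------------------------------
# Pair auto-correlations
# ----------------------------------------------------------------------

_PAC_DOT, _PAC_COS2, _PAC_SHIFTED = 0, 1, 2


@njit(cache=True)
def _pac_accumulate(comw, vec, ok, box_L, bw, nbins, mode, sums, counts):
    n_frames, n_tw = ok.shape
    for f in range(n_frames):
        for i in range(n_tw):
            if not ok[f, i]:
                continue
            for j in range(i + 1, n_tw):
                if not ok[f, j]:
                    continue
                dx = comw[f, i, 0] - comw[f, j, 0]
                dx -= box_L * np.round(dx / box_L)
                dy = comw[f, i, 1] - comw[f, j, 1]
                dy -= box_L * np.round(dy / box_L)
                b = int(np.sqrt(dx * dx + dy * dy) / bw)
                if b < nbins:
                    dot = (vec[f, i, 0] * vec[f, j, 0]
                           + vec[f, i, 1] * vec[f, j, 1])
                    if mode == 1:
                        val = 2.0 * dot * dot - 1.0
                    elif mode == 2:
                        val = 3.0 * (dot - 2.0 / 3.0)
                    else:
                        val = dot
                    sums[b] += val
                    counts[b] += 1


def pair_correlation(
    traj: Trajectory,
    which: str = "v",
    bin_width: float = 0.2,
    max_r: float | None = None,
    warmup_frac: float = 0.1,
    frame_stride: int = 1,
    nematic_form: str = "cos2theta",
) -> CorrelationCurve:
    """Instantaneous pair auto-correlation vs pair separation.

    ``which`` selects the correlated vector: ``"v"`` the direction of
    motion (zero-speed twitchers skipped), ``"p"`` the polar tail-to-head
    orientation, ``"n"`` the nematic director.  Pairs are binned by the
    minimum-image centre-of-mass separation in bins of ``bin_width`` up
    to half the box edge, frames pooled.

    For the director the default is the 2D headless correlator
    <cos 2 theta>; ``nematic_form`` may instead select ``"dot"``
    (<n_g . n_e> of the canonical directors) or ``"shifted"``
    (<3 (n_g . n_e - 2/3)>, the 3D-style form).
    """
    tr = traj.steady_slice(warmup_frac)
    if max_r is None:
        max_r = tr.box_L / 2.0
    comw = np.ascontiguousarray(tr.com_wrapped())
    mode = _PAC_DOT
    if which == "v":
        vec, ok = tr.directions()
        comw = comw[:-1]
    elif which == "p":
        if tr.polar is None:
            raise ValueError("trajectory carries no orientation data")
        vec = tr.polar
        ok = np.ones(vec.shape[:2], dtype=bool)
    elif which == "n":
        vec = tr.nematic()
        ok = np.ones(vec.shape[:2], dtype=bool)
        mode = {"cos2theta": _PAC_COS2, "dot": _PAC_DOT,
                "shifted": _PAC_SHIFTED}[nematic_form]
    else:
        raise ValueError("which must be one of 'v', 'p', 'n'")
    comw = comw[::frame_stride]
    vec = np.ascontiguousarray(vec[::frame_stride], dtype=np.float64)
    ok = np.ascontiguousarray(ok[::frame_stride])
    nbins = int(round(max_r / bin_width))
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=np.int64)
    _pac_accumulate(comw, vec, ok, tr.box_L, bin_width, nbins, mode,
                    sums, counts)
    value = np.full(nbins, np.nan)
    nz = counts > 0
    value[nz] = sums[nz] / counts[nz]
    x = bin_width * (np.arange(nbins) + 0.5)
    return CorrelationCurve(
        x, value, counts,
        meta={"which": which, "bin_width": bin_width,
              "nematic_form": nematic_form if which == "n" else None},
    )


def raft_length(
    curve: CorrelationCurve, fit_range: tuple[float, float] = (5.0, 20.0)
) -> float:
    """Proto-raft size: exponential decay length of a PAC tail.

    Same fitting contract as :func:`~twitchsim.observables.fit_decorrelation_length`;
    for the nematic PAC the default range starts beyond the smectic
    peak near Dr = 4.
    """
    return fit_decorrelation_length(curve, fit_range)


# ----------------------------------------------------------------------
# Local coverage and number fluctuations
# ----------------------------------------------------------------------

@dataclass
class CoverageField:
    """Per-frame local coverage phi' on a square grid partition."""

    n_grid: int
    window: float           # sub-domain edge length
    counts: np.ndarray      # (frames, n_grid^2) occupancy
    phi: np.ndarray         # (frames, n_grid^2) local coverage
    a_twitch: float


def local_coverage(
    traj: Trajectory, n_grid: int = 10, warmup_frac: float = 0.0
) -> CoverageField:
    """Occupancy and local coverage of each of n_grid^2 sub-domains.

    Each twitcher is assigned to the sub-domain containing its wrapped
    centre of mass; phi' = n_local A_twitch / window^2.  Occupancies sum
    to N on every frame.
    """
    tr = traj.steady_slice(warmup_frac) if warmup_frac else traj
    w = tr.box_L / n_grid
    comw = tr.com_wrapped()
    ix = np.clip((comw[..., 0] / w).astype(np.int64), 0, n_grid - 1)
    iy = np.clip((comw[..., 1] / w).astype(np.int64), 0, n_grid - 1)
    idx = ix * n_grid + iy
    n_frames = tr.n_frames
    counts = np.zeros((n_frames, n_grid * n_grid), dtype=np.int64)
    rows = np.repeat(np.arange(n_frames), tr.n_twitchers)
    np.add.at(counts, (rows, idx.ravel()), 1)
    phi = counts * (tr.a_twitch / w**2)
    return CoverageField(n_grid=n_grid, window=w, counts=counts, phi=phi,
                         a_twitch=tr.a_twitch)


@dataclass
class CoverageDistribution:
    """Normalized histogram P(phi'; phi) of local coverage."""

    edges: np.ndarray
    prob: np.ndarray        # probability mass per bin, sums to 1
    mean_phi: float
    global_phi: float

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def local_coverage_distribution(
    traj: Trajectory,
    n_grid: int = 10,
    bin_width: float | None = None,
    warmup_frac: float = 0.1,
) -> CoverageDistribution:
    """Distribution of local coverage over sub-domains and frames.

    The default bin width is one occupancy quantum
    ``A_twitch / window^2`` so the histogram resolves integer counts.
    The distribution mean equals the global coverage exactly
    (occupancy accounting).
    """
    field = local_coverage(traj, n_grid=n_grid, warmup_frac=warmup_frac)
    phip = field.phi.ravel()
    q = field.a_twitch / field.window**2
    if bin_width is None:
        bin_width = q
    edges = np.arange(0.0, phip.max() + 2 * bin_width, bin_width) - bin_width / 2
    hist, edges = np.histogram(phip, bins=edges)
    prob = hist / hist.sum()
    return CoverageDistribution(
        edges=edges, prob=prob,
        mean_phi=float(phip.mean()), global_phi=traj.coverage,
    )


@dataclass
class FluctuationScaling:
    """Window-occupancy fluctuation scaling DN ~ <N>^mu across sizes."""

    window_sizes: np.ndarray
    mean_occupancy: np.ndarray
    std_occupancy: np.ndarray
    mean_phi: np.ndarray
    std_phi: np.ndarray
    mu: float
    fit_mask: np.ndarray
    reference_exponents: tuple = (0.5, 1.0)
    meta: dict = field(default_factory=dict)


def number_fluctuations(
    traj: Trajectory,
    window_sizes=None,
    warmup_frac: float = 0.1,
    fit_fraction: float = 0.5,
) -> FluctuationScaling:
    """Occupancy fluctuations across window sizes and their exponent mu.

    For each window edge l (must divide the box edge) the mean and
    standard deviation of the window occupancy are taken over windows
    and post-warm-up frames; ``mu`` is the log-log slope of DN vs <N>
    restricted to the largest ``fit_fraction`` of the log-abscissa
    range (the dense, large-phi' limit).  Reference exponents 1/2
    (central limit) and 1 (giant number fluctuations) are carried
    alongside.
    """
    L = traj.box_L
    if window_sizes is None:
        window_sizes = [l for l in (4, 5, 10, 20, 25)
                        if abs(L / l - round(L / l)) < 1e-9 and l <= L / 2]
    window_sizes = np.asarray(sorted(window_sizes), dtype=float)
    if window_sizes.size < 3:
        raise ValueError("need at least 3 window sizes")
    meanN = np.empty(window_sizes.size)
    stdN = np.empty(window_sizes.size)
    for k, l in enumerate(window_sizes):
        ng = int(round(L / l))
        if ng < 1 or abs(ng * l - L) > 1e-6 * L:
            raise ValueError(f"window size {l} does not divide the box edge {L}")
        field = local_coverage(traj, n_grid=ng, warmup_frac=warmup_frac)
        meanN[k] = field.counts.mean()
        stdN[k] = field.counts.std()
    phi_scale = traj.a_twitch / window_sizes**2
    if np.all(stdN == 0) or np.all(meanN == 0):
        mu = math.nan
        mask = np.zeros(window_sizes.size, dtype=bool)
    else:
        logm = np.log(meanN)
        thresh = logm.max() - fit_fraction * (logm.max() - logm.min())
        mask = (logm >= thresh) & (stdN > 0)
        if np.count_nonzero(mask) < 2:
            # too few sizes land in the upper half: use the largest two
            mask = np.zeros_like(mask)
            order = np.argsort(logm)
            mask[order[-2:]] = stdN[order[-2:]] > 0
        if np.count_nonzero(mask) < 2:
            raise ValueError("fewer than 2 window sizes in the fit range")
        mu = float(np.polyfit(logm[mask], np.log(stdN[mask]), 1)[0])
    return FluctuationScaling(
        window_sizes=window_sizes,
        mean_occupancy=meanN,
        std_occupancy=stdN,
        mean_phi=meanN * phi_scale,
        std_phi=stdN * phi_scale,
        mu=mu,
        fit_mask=mask,
        meta={"fit_fraction": fit_fraction, "warmup_frac": warmup_frac},
    )
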