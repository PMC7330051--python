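# Methods

## The model

`twitchsim` simulates twitching-motility bacilliforms as stiff
bead-spring rods on a two-dimensional surface.  Each cell is a chain of
four Langevin spheres (diameter sigma, mass m) joined by FENE bonds
(k_F = 50, R0 = 1.5) and kept straight by harmonic three-body bending
(k_H = 33, theta_0 = pi); all sphere pairs, bonded ones included,
repel through the WCA potential (epsilon = 1, cut-off 2^(1/6) sigma).
Spheres obey the underdamped Langevin equation

    m x'' = -zeta x' - grad V + xi,

with zeta = 1 and Gaussian noise xi satisfying fluctuation-dissipation
at k_B T = 2e-7.  That temperature is deliberately negligible: surface
bacteria are driven by motility noise, not heat; the thermal term is
nevertheless implemented and covered by an Einstein-relation test at
artificial k_B T = 0.5.  All quantities are in reduced units; the time
unit is tau = sqrt(m sigma^2 / epsilon) and the integration step is
dt = 0.01 tau.

Self-propulsion follows a stochastic three-phase pilus cycle per cell:

* **rest** - passive; probability 0.1 per tau of starting an extension
  (drawn on tau boundaries, so rests are geometric with mean 10 tau);
* **extension** - passive for exactly 10 tau, after which a "dummy
  pilus" anchor is fixed in the lab frame a distance L0 = 2.4 from the
  head sphere, at a uniform random angle within +-pi/4 of the body
  axis;
* **retraction** - the head is pulled toward the anchor with a
  constant-magnitude force k_P = 1 (zero inside the cut-off r0 = 0.2)
  until the head arrives (distance < L_R = 0.2), the pilus snaps
  (distance > L_S = 3) or the adhesion is exhausted (after t_M =
  70 tau).  Termination is checked every integration step with
  priority arrive > snap > exhaust; the cell then rests with no memory
  of the old pilus.

A free chain dragged at the head by unit force moves at the terminal
speed k_P / (4 zeta) = 0.25, so an unobstructed retraction covers
L0 - L_R = 2.2 sigma in roughly 10 tau; the packaged deterministic
experiment (`retraction_arrival_time`) gives 9.8 tau.

### Conventions that the equations leave open

* **Pilus force sign.**  Read literally, the linear pilus potential
  -k_P (r - r0) has a gradient pointing away from the anchor.  The
  force is implemented as a constant-magnitude pull *toward* the
  anchor, which is the unambiguous physical description of a
  retracting pilus; the potential is its antiderivative
  k_P (r - r0) for r > r0.
* **Centre of mass.**  Per-twitcher position and velocity are means
  (not sums) over the four spheres; with sums every displacement
  statistic would simply carry a constant factor 4.
* **Head/tail.**  Sphere 0 is the tail, sphere 3 the head; the polar
  vector p points tail to head and the pilus attaches to the head.
* **Nematic director.**  Directors are stored canonically with
  n_x >= 0 (ties: n_y >= 0), so n and -n coincide.
* **Zero velocity.**  The direction of motion is undefined for a
  twitcher that did not move in a tau interval; such samples are
  excluded from direction correlators rather than recorded as NaN.

## Integration and neighbour search

The integrator is the Gronbech-Jensen/Farago discretisation, which
treats the linear drag term exactly; with m/zeta = tau and dt =
0.01 tau it reproduces the closed-form relaxation of a constant-force
chain to better than 1e-4 over 10 tau (tested).  Pair interactions use
a Verlet list built from linked cells (cell edge >= 1.5 sigma) with a
0.4 sigma skin, rebuilt whenever any sphere has moved more than half
the skin; list-based forces agree with the brute-force all-pairs sum
to machine precision (tested at 1e-12 relative).  Noise is pre-drawn
per unit-time chunk from a dedicated PCG64 stream.  A run is fully
determined by `(params, seed)`: the seed spawns independent
sub-streams for initialisation, motility draws (ordered by twitcher
index on each tau boundary) and thermal noise.

Initial configurations place straight rods by rejection sampling
(coverage <= 0.3; a trial is rejected if any sphere pair exceeds 10
epsilon of WCA energy) or, for denser systems, on an aligned lattice
with random polarity followed by a 1000-tau randomising warm-up, after
which phases are reset and the unwrapped origin re-zeroed.  Both
wrapped and unwrapped coordinates are carried; bodies that straddle a
periodic boundary keep coherent unwrapped coordinates so centre-of-mass
and orientation are always well defined.

## Observables

Frames are sampled once per tau (the analysis definitions of velocity
and direction of motion presuppose this cadence).  The suite computes:

* **MSD / NGP** - Dr^2(t) and Dr^4(t) over all time origins and
  twitchers on a log-spaced lag grid (~20 points per decade);
  alpha_2 = (d/(d+2)) Dr^4/ (Dr^2)^2 - 1 with d = 2.  The scaling
  exponent beta is a log-log least-squares slope; default windows are
  [1, 10] tau (short) and [1e3 tau, span/2] (long).  The long window
  extends to half the span because the correlated-to-diffusive
  crossover of this motility cycle sits near 1e3-1e4 tau (orientation
  persistence is ~8e2 tau); a fit confined to [1e3, 1e4] tau straddles
  the crossover and reads ~1.3 rather than the asymptotic 1.
* **van Hove** G(Dx, t) - 1D displacements pooled over both axes, with
  a matched-variance Gaussian reference and the diffusive collapse
  transform (Dx t^-1/2, G t^1/2).
* **MSV / diffusivity** - V^2 = Dr^2(tau)/tau^2; script-D from the
  linear MSD regime beyond t_min = 1e4 tau divided by 2d; relative
  diffusivity D = script-D / (tau V^2).
* **IAC** - rho(Dr) = <v(0).v(Dr)> along each twitcher's own path.
  "Distance travelled" is read literally as cumulative path length at
  tau resolution; the correlation for each Dr bin is taken at the
  first sample whose path reaches it.  A net-displacement variant sits
  behind `abscissa="net"`.  Decorrelation lengths come from
  least-squares fits of log rho over a stated tail range (default
  Dr in [20, 80]).
* **PAC** - instantaneous pair correlators of v, p or n binned by
  minimum-image centre-of-mass separation (bin width 0.2 sigma, up to
  half the box).  The nematic correlator defaults to the standard 2D
  headless form <cos 2 theta>; the raw director dot product and the
  3D-style form 3(<n.n> - 2/3) are available behind
  ``nematic_form`` because raw dot products of sign-indeterminate
  directors are ill-defined.  The proto-raft size is the exponential
  decay length of the nematic PAC tail fitted beyond the smectic peak
  (default range [5, 20] sigma).
* **Coexistence / number fluctuations** - local coverage phi' over a
  square sub-domain grid (default 10 x 10); occupancy fluctuation
  scaling DN ~ <N>^mu across window sizes that divide the box, with mu
  fitted on the upper half of the log-abscissa range (falling back to
  the largest two sizes when fewer land there) and the reference
  exponents 1/2 (central limit) and 1 (giant number fluctuations)
  carried alongside.

Steady-state statistics (speeds, PAC, coexistence, fluctuations)
exclude an initial warm-up fraction of frames, 10% by default and
configurable per call; MSD-type statistics use all origins.

## Synthetic fixtures

The `synthetic` module generates trajectories with closed-form
statistics used as independent oracles: ballistic motion (MSD = v^2
t^2), Brownian motion (MSD = 4 D0 t, alpha_2 = 0), fixed-length
random-direction steps (alpha_2 = -1/2, the platykurtic bound),
a 50/50 zero/Gaussian step mixture (alpha_2 = 1), a persistent random
walk (direction correlation exp(-D_rot t), decay length v/D_rot),
uniform re-placement fields (mu = 1/2) and single-cluster fields in
which a common density factor dominates window occupancy (mu -> 1 at
large occupancy).  These fixtures are points, not rods: they carry no
excluded volume, orientation dynamics or motility cycle, so passing
the oracle tests validates the estimators, not the simulator; the
simulator itself is validated against the deterministic mechanics
tests and the published solitary-twitcher statistics.

## Problem sizes

Published ensemble runs use a box of edge 100 with up to N = 2000
twitchers for 1e6 tau.  The packaged test suite and acceptance script
reproduce the solitary-twitcher statistics on runs of 2-4e5 tau
(the acceptance script uses a single twitcher for 4e5 tau; the test
suite averages 12 non-interacting twitchers at coverage 2e-4 in a box
of edge 900, which reproduces solitary dynamics with sharper long-lag
statistics).  Collective behaviour below the critical coverage is
checked on a box of edge 50 (N = 66-125, runs of 0.8-1.2e4 tau);
sub-domains there keep the 10-sigma window edge (a 5 x 5 grid).  The
dense case (coverage 0.57) uses the full box edge 100 for 8e3 tau:
on the half-size box the dense cluster percolates and the dilute/dense
coverage peaks smear into a shoulder (mu saturates near 0.65), whereas
the full-size box reproduces the dilute/dense coexistence modes, the
giant-number-fluctuation exponent and the smectic nematic peak already
at this much-reduced duration.  Coverage statistics on these boxes are
steady-state: quarters of runs several times longer agree.  All sizes
were chosen so the full suite completes on a single desktop core.

## Known limitations

* Strictly 2D, stiff bodies of fixed length; no reproduction,
  secretions, nutrient fields, hydrodynamics or multiple motility
  modes.
* One effective pilus per cell with fixed extension length and
  deterministic extension time; real pili have stochastic lengths and
  retraction kinetics.
* The coarse lattice initialisation requires coverage <= 0.8.
* On the reduced analysis box the dense-phase coverage peak is
  broadened by counting noise; quantitative coexistence densities
  should be measured on the full-size box.
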