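# twitchsim

Coarse-grained simulation and statistical analysis of **twitching-mode
bacilliform bacteria** in two dimensions.

Rod-shaped surface bacteria such as *Pseudomonas aeruginosa* crawl by
repeatedly extending, anchoring and retracting type-IV pili.  This
package implements an agent-based model of that motility mode — each
cell is a stiff chain of four Langevin spheres driven by a stochastic
rest / pilus-extension / pilus-retraction cycle with a single effective
("dummy") pilus — together with the statistics used to characterise
individual and collective twitching dynamics: mean squared
displacement and its scaling exponent, the non-Gaussian parameter, van
Hove step-size distributions, direction auto- and pair-correlations,
local-coverage coexistence distributions and giant number
fluctuations.  It is aimed at soft-matter and biophysics researchers
studying collective motility, and at experimentalists wanting
reference statistics for tracking data.

## Model summary

Each sphere obeys the underdamped Langevin equation

```
m ẍᵢ = −ζ ẋᵢ − ∇V + ξᵢ ,      V = V_WCA + V_FENE + V_bend + V_pilus
```

in a square periodic box, in reduced units (σ = m = ε = 1, τ =
√(mσ²/ε), dt = 0.01 τ, k_BT = 2·10⁻⁷).  The motility cycle: a resting
cell starts extending with probability 0.1 per τ; after exactly 10 τ
the pilus anchors at distance L₀ = 2.4 from the head within a ±π/4
cone about the body axis; during retraction the head is pulled toward
the anchor with constant force k_P = 1 until arrival (r < 0.2), snap
(r > 3) or exhaustion (t > 70 τ).  Coverage fraction φ = N·A/L² with
A = 3 + π/4 ≈ 3.7854; the critical coverage φ* = A/(π(L_body/2)²) ≈
0.30 marks the onset of collective dynamics.

## Worked example

Simulate a solitary twitcher for 2·10⁴ τ and inspect its displacement
statistics:

```python
from twitchsim import SimulationParams, simulate, msd, ngp, fit_beta

params = SimulationParams(n_twitchers=1, total_steps=2_000_000, seed=9)
traj, report = simulate(params)
print(report.event_counts)

curve = msd(traj)
print("beta (short lags [1,10] tau):", round(fit_beta(curve, (1, 10)), 3))
alpha2 = ngp(curve)
print("alpha2 at t<=5 tau:", round(alpha2.value[alpha2.x <= 5].mean(), 3))
```

prints

```
{'REST_EXIT': 687, 'ANCHOR_PLACED': 687, 'ARRIVE': 687, 'SNAP': 0, 'EXHAUST': 0}
beta (short lags [1,10] tau): 1.853
alpha2 at t<=5 tau: 0.541
```

Every retraction of an unobstructed twitcher ends by arrival (snap and
exhaustion only occur in crowded systems).  The short-lag MSD exponent
near 2 signals propulsive motion dominated by single retractions, and
the positive non-Gaussian parameter (≈ 0.5, against 0 for a Gaussian
walk) reflects the mixture of resting and actively translocating
cells; both converge toward the published solitary-twitcher values on
longer runs.

The same workflow runs from a shell:

```bash
twitch simulate --n 1 --steps 2000000 --seed 9 --out solo.extxyz
twitch analyze msd --traj solo.extxyz --out msd.csv
twitch analyze pac --traj solo.extxyz --which n --out pac_n.csv
```

Trajectories are a human-readable extended-XYZ dialect; observables
are CSV tables with `# key=value` metadata headers.

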