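# mlipal

Active learning for reactive surrogate potentials, with the free-energy
toolchain to judge the result — on analytic benchmark surfaces that stand in
for an electronic-structure oracle.

## The problem

Training a machine-learned interatomic potential (MLIP) for a chemical
reaction needs configurations from *both* basins and the transition region
between them, yet unbiased dynamics at the temperatures of interest never
crosses the barrier.  This package implements an automated active-learning
(AL) cycle that couples surrogate-driven molecular dynamics with
well-tempered metadynamics (WTMetaD): Gaussian hills of height
h = h₀·exp(−V(s)/(k_B(γ−1)T)) are deposited on a collective variable (CV)
every τ fs, pushing the walker over barriers; the last frame of each n³+2 fs
run is vetted by a selector (energy deviation from the oracle, or descriptor
similarity to the training set) and, if informative, labelled and added to
the training set before retraining.  In the inherited-bias variant
(WTMetaD-IB) the bias is carried across AL iterations — the hills of the n
parallel runs are summed with heights scaled by 1/n — and each restart
begins from the training point with the lowest biased energy
E + V_bias(s), steering sampling toward unexplored regions.

Free energies are estimated three ways and cross-checked: umbrella sampling
combined by self-consistent WHAM, the well-tempered relation
F(s) = −γ/(γ−1)·V_bias(s), and final-bias reweighting
(weights ∝ exp(+V_bias(s_t)/k_BT), Gaussian-KDE smoothed).

Everything runs against built-in analytic surfaces — a 1D double well, the
Müller–Brown surface, and a Morse-based triatomic bond-exchange system —
so the full workflow is testable on a laptop with no quantum chemistry.
The intended audience is method developers who want a transparent,
dependency-light reference implementation of the AL/metadynamics loop and
its estimators.

## Worked example

Recover the 0.2 eV barrier of the double well from a well-tempered
metadynamics run, two independent ways:

```python
import numpy as np
from mlipal import (AxisPositionCV, BiasPotential, DoubleWell1D, MDParams,
                    barrier, fes_from_bias, reweight_fes, wtmetad_run)

gt = DoubleWell1D()                       # V(x) = 0.2 eV * ((x/1 Å)² − 1)²
start = gt.make_configuration((-1.0,))    # left minimum
cv = AxisPositionCV(0, 0, name="x")
bias = BiasPotential([cv], h0=0.01, gamma=15, T=300, tau_deposit=100,
                     sigma=0.1)
params = MDParams(timestep=0.5, temperature=300, n_steps=400_000, seed=11)
traj, final_bias = wtmetad_run(start, gt, bias, params, stride=10)

grid = np.linspace(-1.5, 1.5, 301)
f_bias = fes_from_bias(final_bias, grid)
f_rew = reweight_fes(traj, final_bias, T=300, bandwidth=0.02, grid=grid)
for name, f in [("bias relation", f_bias), ("reweighting", f_rew)]:
    dg, ts = barrier(f, (-1.3, -0.7), (0.7, 1.3))
    print(f"{name}: barrier = {dg:.3f} eV at x = {ts:+.2f} Å")
```

Output from this exact script:

```
bias relation: barrier = 0.196 eV at x = -0.04 Å
reweighting: barrier = 0.197 eV at x = -0.02 Å
```

Both estimators land within a few percent of the analytic 0.2 eV after
200 ps of biased sampling (2000 hills), and the transition state sits at
the barrier top x ≈ 0, as it should for this symmetric well.

An active-learning run is one call:

```python
from mlipal import ALConfig, WallRestraint, run_al

walls = [WallRestraint(cv, -1.6, 1.6, kappa=10.0)]
cfg = ALConfig(mode="wtmetad-ib", seed=1, energy_threshold=0.02, h0=0.02)
result = run_al(cfg, gt, start, cvs=[cv], walls=walls)
print(result.manifest["iterations"], result.manifest["dataset_size"],
      result.manifest["ground_truth_calls"])
```

which on this seed prints `41 20 172`: 41 iterations, a 20-configuration
training set, 172 oracle calls in total — and a surrogate whose own
constrained-scan barrier is within 5% of the true one.

There is also a small CLI (`mlipal al run`, `mlipal md run`,
`mlipal fes wham|metad|reweight`, `mlipal classify`,
`mlipal fixtures make`) driven by a validated YAML configuration; see
`mlipal --help`.

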