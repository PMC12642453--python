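# Methods

## Scope and model of the problem

`mlipal` implements an automated active-learning (AL) workflow for training
reactive surrogate potentials — machine-learned interatomic potentials
(MLIPs) in spirit — together with the free-energy toolchain used to judge
them: umbrella sampling combined by WHAM, well-tempered metadynamics
(WTMetaD) with bias-based and reweighting-based free-energy estimates, and
predicate-based trajectory classification.  Everything runs against
analytic ground-truth surfaces, so the entire loop — labelling, training,
biased dynamics, selection, retraining — is exercised end to end offline.

Units are Å, eV, fs, K and amu throughout, with
kB = 8.617333262×10⁻⁵ eV K⁻¹.  The natural time unit
τ₀ = √(amu Å²/eV) ≈ 10.1805 fs links the mechanical units; a Langevin
friction quoted as 0.02 per natural time unit is 0.02/τ₀ ≈ 1.96×10⁻³ fs⁻¹,
the package default.

## Ground-truth fixtures

Three analytic surfaces stand in for an electronic-structure oracle.  Each
acts on designated coordinates of ordinary 3D configurations (the rest are
masked by `frozen_axes`), so the downstream stack is identical to what a
molecular system would use.  The fixture particle is carbon-like
(12.011 amu): thermal velocities then match heavy-atom reaction
coordinates rather than a 1 amu dummy, which matters for how far a walker
travels per MD run.

* **DoubleWell1D** — V(x) = h_b((x/w)² − 1)², defaults h_b = 0.2 eV,
  w = 1 Å.  Since the only mobile coordinate is x, the free-energy profile
  along x equals V exactly, making the 0.2 eV barrier an exact reference
  for every estimator.
* **MuellerBrown2D** — the standard four-Gaussian test surface on (x, y).
  Raw units are arbitrary; a scale of 5×10⁻³ eV per raw unit puts
  kBT(300 K) ≈ 5.2 raw units, a thermally meaningful regime.  The three
  minima and their energies reproduce the literature values
  (−146.70, −108.17, −80.77 raw) by grid search.
* **TriatomicExchange** — A–B–C bond exchange,
  V = M(r_AB) + M(r_BC) + C_rep·exp(−α[(r_AB−r0)² + (r_BC−r0)²]),
  M a Morse curve.  Two off-diagonal basins (A–B vs B–C bonded) exist only
  when the both-bonds-formed point is destabilised strongly enough, which
  requires α·C_rep > D·a²; the defaults D = 1 eV, a = 1.5 Å⁻¹,
  r0 = 1.6 Å, C_rep = 2 eV, α = 2 Å⁻² give symmetric basins at
  r_AB − r_BC ≈ ±1.29 Å and a 0.319 eV exchange barrier (400-point
  constrained scan).

## Surrogate model

The trainable potential is kernel ridge regression with an RBF kernel on a
permutation- and rotation-invariant descriptor: one channel per unordered
element pair holding all exp(−r/r_scale) values sorted descending,
zero-padded to a fixed length.  For the designated-coordinate fixtures the
descriptor is simply the vector of mobile coordinates (the exact
featurisation of those surfaces).  Energies are centred before fitting;
the length-scale defaults to the median pairwise descriptor distance of
the training set; the ridge is 10⁻⁸.  Forces come from the analytic chain
rule through the descriptor, with a central-difference fallback
(10⁻⁴ Å step) when sorted-channel ties (< 10⁻¹⁰) make the Jacobian
ambiguous.  The fit is energy-only; force labels are stored and available
to alternative regressors, which can be swapped in via the
`train`/`predict` contract.  Two optional robustness devices —
train-time energy clamping (`energy_clip`) and a training-window filter
(`max_label_above_min`) — exist but default off; on the benchmark
campaigns they degraded walker behaviour more than they helped the fit.

## Dynamics

Langevin dynamics uses the BAOAB splitting, which gives accurate
configurational sampling at the default 0.5 fs timestep; with zero
friction (or the `nve` ensemble) the scheme reduces to velocity Verlet
exactly.  Velocities are Maxwell–Boltzmann at the run temperature; frozen
axes carry neither velocity nor force.  A non-finite energy or force
truncates the trajectory with an `unstable` flag instead of raising: the
AL loop must survive and learn from unstable early-generation surrogates.
Energy conservation is monitored as the least-squares slope of total
energy versus time; the double well at 0.1 fs drifts below
10⁻⁴ eV ps⁻¹ over 10 ps.

## Well-tempered metadynamics and inherited bias

The bias is a sum of Gaussian hills on CV space with tempered heights
h = h0·exp(−V(s)/(kB(γ−1)T)).  Hills are deposited every `tau_deposit` fs
at the walker's current CV value; the tempering sees the *total* bias
including inherited hills, so a warm-started run does not re-deposit what
it inherited (config-switchable via `temper_on_total_bias`).  Bias
evaluation is exact summation over hills (vectorised); no grid caching is
needed at the problem sizes the package targets.

Inherited-bias averaging follows the 1/n rule: the hills shared by all
parallel runs (the inherited prefix, recognised by object identity) enter
once at full height; each run's newly deposited hills enter at height/n.
The next iteration's starting configuration is the dataset item with the
lowest biased energy (true energy plus bias at its CV value), computed
fresh from stored coordinates.

Two readings of the loop's restart semantics are implemented.  The default
persists each trajectory's phase space, bias and run index across
rejection iterations and restarts everything after a retraining event
(`restart_scope="all"`); alternatives restart only the selected
trajectories (`"selected"`) or, for inherited-bias mode, restart from the
best dataset point every iteration (`ib_restart_each_iteration=True`).
The defaults reproduce the efficiency ordering reported for the method
(inherited bias no more expensive than plain metadynamics AL) on the
fixtures.

## Active learning

A run starts from 5–10 uniformly displaced copies (default 8, ±0.1 Å per
coordinate) of an input structure, labelled and fitted.  Each of
`n_parallel` (default 4) trajectories then runs n³+2 fs, where n is that
trajectory's run index starting at 0; only the last frame is judged.  The
energy selector labels the frame (the oracle call is never wasted) and
selects when |E_true − E_model| exceeds the threshold, interpreted as a
*total* energy in eV; the similarity selector selects when the maximum
descriptor cosine similarity to the dataset falls below its threshold
(default 0.9995) and labels only on selection.  Rejection increments n;
selection triggers retraining from scratch (datasets are small) and, in
inherited-bias mode, the 1/n averaging.  The loop stops when every
trajectory's next run would exceed `max_md_time` (default 1000 fs,
reached at n = 10) or after `max_iterations` (default 50).  Three
consecutive iterations in which every trajectory is unstable and nothing
is selected abort the run.

Default selector thresholds are 0.1 eV (energy) and 0.9995 (similarity);
default hill parameters for AL are h0 = 0.013 eV, γ = 50, σ = 0.1 CV
units, τ = 25 fs; AL temperatures are 500 K for downhill sampling and
300 K for the metadynamics modes.

## Free-energy estimators

* **Umbrella sampling / WHAM.**  Windows restrain the CV with
  w(ξ) = ½k(ξ−ξᵢ)² (the ½-convention is recorded as `harmonic_half: true`
  in estimator metadata).  WHAM iterates the standard self-consistent
  equations to a window-offset tolerance of 10⁻⁷ eV on a 200-bin grid
  (default) padded 2% beyond the sampled range.
* **Bias relation.**  F(s) = −γ/(γ−1)·V_bias(s), min-shifted; the γ→∞
  limit recovers F = −V_bias.
* **Final-bias reweighting.**  Samples s_t are weighted
  ∝ exp(+V_final(s_t)/kBT) and smoothed by a Gaussian KDE of bandwidth
  0.02 CV units (default); F = −kBT ln p.
* **Replicated production runs** report the across-replica mean and
  standard deviation; the 95% band is 1.96·σ/√reps.  Unstable replicas
  are dropped, erroring when more than half are lost.
* **Barrier extraction** takes explicit basin intervals, returns
  ΔG = max F between the basin minima minus min F in the departure basin,
  and the CV location of the maximum.
* **Trajectory classification** evaluates a conjunction of interatomic
  distance thresholds frame by frame; a trajectory counts when any frame
  satisfies all conditions.  The fraction carries a Wilson-score 95%
  interval.

The exact-sampling oracle `boltzmann_samples` draws from the biased 1D
Boltzmann density by inverse-CDF interpolation on a dense grid; it is the
reference against which WHAM is validated (12 windows spanning ±1.6 Å,
k = 2 eV Å⁻², 1.5×10⁵ draws per window, 400 bins, recovering a 5 kBT
double well to < 0.3 kBT).

## Benchmark campaign design (`mlipal.benchmarks`)

These frozen experiment definitions back both the test suite and
`scripts/acceptance.py`.

* **Efficiency/coverage comparison** (double well and triatomic): energy
  thresholds are scaled to each surface's barrier at the same ≈0.1 ratio
  the canonical 0.1 eV threshold bears to a ~1 eV reaction barrier
  (0.02 eV and 0.03 eV respectively); hills are h0 = 0.02 eV ≈ kBT with
  σ = 0.1 and τ = 25 fs; sampling walls bracket the reactive range
  (|x| ≤ 1.6 Å on the well; bond lengths 1.2–4.0 Å plus an end-atom
  separation wall on the triatomic).  Eight seeds per mode; the triatomic
  uses a 120-iteration budget because 1/n averaging dilutes its frontier
  hills fourfold, slowing the climb over the 0.32 eV barrier.  Coverage is
  assessed on the pooled inherited-bias training CVs of the repetition
  experiment; per-seed gaps are also reported and are wider (a single
  50-iteration run yields a handful of transit-era points between the
  basins).
* **Surrogate fidelity**: after inherited-bias AL on the double well, the
  barrier of the *surrogate* is measured by a 200-point constrained scan
  and compared with h_b.  The Müller–Brown campaign is seeded with eight
  displaced copies of each of the two deep minima — the usual situation
  where reactant- and product-like geometries are known — with the
  selector threshold at half the 2-raw-unit accuracy target and stiff
  walls (κ = 300 eV Å⁻²) boxing the thermally relevant domain; the budget
  is 200 oracle calls in total.  Seeding from a single minimum makes
  discovery of the second deep basin (0.53 eV of 2D bias fill away) a
  coin flip at this budget, which is a statement about the budget, not
  the method.
* **Metadynamics free-energy recovery**: five independent 200 ps runs on
  the double well (γ = 15, h0 = 0.01 eV, σ = 0.1 Å, τ = 100 fs, 300 K);
  barriers from the bias relation and from reweighting agree with the
  analytic 0.2 eV within 10%, and the two profiles agree within 0.5 kBT
  over the inter-basin range.

## What the fixtures do and do not show

The analytic surfaces are low-dimensional, smooth, and noise-free; their
exact per-configuration labels and tiny descriptor spaces make kernel
interpolation far easier than for a real molecule, so training-set sizes
and accuracy figures here do not transfer to electronic-structure
problems.  What does transfer is the *relative* behaviour the package is
built to demonstrate: tempered hills saturate, inherited bias removes
re-deposition waste, the lowest-biased-energy restart pushes sampling to
the frontier, and independent free-energy estimators agree when sampling
is adequate.  Explicit solvent, periodic boundary conditions, force-matched
training and real descriptor families (SOAP, ACE) are all outside the
desk-scale scope; the model and sampler contracts are the extension
points for them.

## Numerical choices and degenerate inputs

Coincident atoms (r < 10⁻⁹ Å) raise a domain error in distance-based CVs.
The coordination-number switching function is evaluated in its simplified
form 1/(1 + (r/r0)⁶), removing the 0/0 at r = r0.  Kernel systems are
solved by Cholesky with a least-squares fallback for singular cases.
WHAM bins with zero counts yield +∞ free energy and are excluded from
min-shifting.  Restart ties (equal biased energies) resolve to the
earliest-inserted dataset item.  Duplicate training rows are suppressed by
a max-atom-displacement tolerance (10⁻⁶ Å by default) during AL.
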