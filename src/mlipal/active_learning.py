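"""Active-learning loop for training reactive surrogate potentials.

The cycle: label a handful of randomly displaced copies of an input
structure, train an initial surrogate, then repeatedly propagate several
parallel surrogate-MD trajectories — unbiased from a transition-state-like
structure ("downhill"), with well-tempered metadynamics ("wtmetad"), or
with metadynamics plus a bias inherited across iterations ("wtmetad-ib").
Each trajectory runs for n³ + 2 fs, where n is that trajectory's MD-run
index starting at zero.  The last frame of each run is judged by a
selector; selected frames are ground-truth labelled and added to the
training set, the model is retrained, and (in inherited-bias mode) the
iteration's per-run biases are 1/n-averaged into the next iteration's
starting bias.  The loop ends when every trajectory's next run would
exceed the maximum MD time (1 ps by default) or after a maximum number of
iterations (50 by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .configurations import Configuration, Dataset, dataset_append_unique, random_displace
from .dynamics import DEFAULT_FRICTION, MDParams, init_velocities, run_md
from .metadynamics import BiasPotential, average_biases, select_restart, wtmetad_run
from .surrogate import DescriptorSpec, SurrogateModel, similarity

_MODES = ("downhill", "wtmetad", "wtmetad-ib")


def md_duration(n: int) -> float:
    """Length of the n-th MD run of a trajectory, in fs: n³ + 2."""
    if n < 0:
        raise ValueError("run index n must be >= 0")
    return float(n**3 + 2)


@dataclass
class ALConfig:
    """Active-learning run settings; defaults follow the workflow's canon.

    ``temperature`` defaults to 500 K for downhill sampling and 300 K for
    the metadynamics modes when left unset.  The energy-selector threshold
    is a *total* energy difference in eV.  ``reset_n_on_selection``
    controls whether trajectory run indices restart from zero after a
    retraining event.  ``temper_on_total_bias`` makes the well-tempered
    height decay see inherited hills as part of V(s, t).
    """

    mode: str = "wtmetad-ib"
    init_count: int = 8
    init_magnitude: float = 0.1          # Å
    temperature: float | None = None     # K
    n_parallel: int = 4
    max_md_time: float = 1000.0          # fs
    max_iterations: int = 50
    selector: str = "energy"             # "energy" | "similarity"
    energy_threshold: float = 0.1        # eV (total)
    similarity_threshold: float = 0.9995
    # metadynamics bias parameters
    h0: float = 0.013                    # eV
    gamma: float = 50.0
    sigma: float | tuple = 0.1           # CV units
    tau_deposit: float = 25.0            # fs
    # dynamics
    timestep: float = 0.5                # fs
    friction: float = DEFAULT_FRICTION   # fs⁻¹
    md_stride: int = 2
    # model
    descriptor_r_scale: float = 1.0
    descriptor_pad: int = 16
    ridge: float = 1e-8
    energy_clip: float | None = None     # eV above dataset min (see model)
    # bookkeeping
    dedup_tol: float = 1e-6              # Å
    # energy window: selected frames labelled more than this many eV above
    # the current dataset minimum are logged but kept out of the training
    # set (standard practice to keep kernel fits well-conditioned); None
    # disables the window
    max_label_above_min: float | None = None
    reset_n_on_selection: bool = True
    # which trajectories restart after a retraining event: "selected" keeps
    # the non-selected walkers' phase space, bias and run index untouched
    # (per-trajectory reading of the rejection rule); "all" restarts every
    # walker from its mode-specific starting point
    restart_scope: str = "all"
    temper_on_total_bias: bool = True
    # inherited-bias mode variant: True restarts every iteration from the
    # lowest-biased-energy dataset point and 1/n-averages the run biases
    # every iteration; the default keeps the persisted-trajectory semantics
    # (restart and average only after a retraining event)
    ib_restart_each_iteration: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.selector not in ("energy", "similarity"):
            raise ValueError("selector must be 'energy' or 'similarity'")
        if self.energy_threshold <= 0 or self.similarity_threshold <= 0:
            raise ValueError("selector thresholds must be positive")
        if self.max_md_time < 2:
            raise ValueError("max_md_time must be >= 2 fs")
        if self.restart_scope not in ("selected", "all"):
            raise ValueError("restart_scope must be 'selected' or 'all'")
        if self.n_parallel < 1:
            raise ValueError("n_parallel must be >= 1")
        if self.temperature is None:
            self.temperature = 500.0 if self.mode == "downhill" else 300.0

    def make_bias(self, cvs) -> BiasPotential:
        return BiasPotential(cvs, h0=self.h0, gamma=self.gamma,
                             T=self.temperature, tau_deposit=self.tau_deposit,
                             sigma=self.sigma)


class CountingGroundTruth:
    """Wraps a ground-truth oracle and counts its evaluations."""

    def __init__(self, gt):
        self.gt = gt
        self.calls = 0

    def label(self, c: Configuration) -> Configuration:
        self.calls += 1
        return self.gt.label(c)

    def energy_forces(self, c: Configuration):
        self.calls += 1
        return self.gt.energy_forces(c)


@dataclass
class _TrajState:
    """Persisted phase-space state of one parallel trajectory."""

    index: int
    n: int = 0
    positions: np.ndarray | None = None
    velocities: np.ndarray | None = None
    bias: BiasPotential | None = None
    deposit_phase: float = 0.0
    needs_restart: bool = True
    unstable: bool = False


@dataclass
class ALState:
    iteration: int = 0
    dataset: Dataset = field(default_factory=Dataset)
    model: SurrogateModel | None = None
    inherited_bias: BiasPotential | None = None
    trajs: list[_TrajState] = field(default_factory=list)
    gt_calls_at_last_check: int = 0
    consecutive_dead_iterations: int = 0
    log: list[dict] = field(default_factory=list)

    def record(self, **event) -> None:
        self.log.append(event)


def energy_selector(candidate: Configuration, model: SurrogateModel, gt,
                    threshold: float):
    """Label ``candidate`` and select it when |E_true − E_model| > threshold.

    The labelled configuration is returned either way — the ground-truth
    call is never wasted.
    """
    labelled = gt.label(candidate)
    e_pred = model.predict_energy(candidate)
    selected = abs(labelled.energy - e_pred) > threshold
    return selected, labelled


def similarity_selector(candidate: Configuration, ds: Dataset,
                        spec: DescriptorSpec, threshold: float) -> bool:
    """Select a candidate whose maximum similarity to the dataset is below
    the threshold (i.e. the candidate is sufficiently novel).  No
    ground-truth call is made here."""
    if len(ds) == 0:
        raise ValueError("similarity selector needs a non-empty dataset")
    best = None
    for item in ds:
        try:
            s = similarity(spec, candidate, item)
        except ValueError:
            continue
        best = s if best is None else max(best, s)
    if best is None:
        # composition matches nothing in the dataset: maximally novel
        return True
    return best < threshold


def al_iteration(state: ALState, cfg: ALConfig, gt, initial: Configuration,
                 cvs, walls=(), rng: np.random.Generator | None = None,
                 spec: DescriptorSpec | None = None) -> ALState:
    """Run one active-learning iteration in place; returns ``state``.

    Each parallel trajectory either continues from its persisted
    phase-space point or, after a retraining event, restarts according to
    the mode: downhill from a freshly displaced copy of the input
    (TS-like) structure with new Maxwell–Boltzmann velocities and no bias;
    wtmetad from the input structure with an empty bias; wtmetad-ib from
    the dataset point of lowest biased energy with the inherited bias.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    spec = spec or DescriptorSpec(cfg.descriptor_r_scale, cfg.descriptor_pad)
    selections = []
    any_ok = False
    ib_per_iter = cfg.mode == "wtmetad-ib" and cfg.ib_restart_each_iteration

    for traj in state.trajs:
        if ib_per_iter:
            traj.needs_restart = True
        if traj.needs_restart:
            if cfg.mode == "downhill":
                start = random_displace(initial, 1, cfg.init_magnitude,
                                        rng=rng)[0]
                traj.bias = None
            elif cfg.mode == "wtmetad":
                start = initial.copy()
                traj.bias = cfg.make_bias(cvs)
            else:  # wtmetad-ib
                base = state.inherited_bias or cfg.make_bias(cvs)
                start = select_restart(state.dataset, base, cvs).copy(
                    energy=None, forces=None
                )
                traj.bias = base.spawn()
            traj.positions = start.positions.copy()
            traj.velocities = init_velocities(start, cfg.temperature, rng=rng)
            traj.deposit_phase = 0.0
            traj.needs_restart = False
        start = initial.copy(positions=traj.positions.copy(),
                             energy=None, forces=None)

        duration = md_duration(traj.n)
        n_steps = max(int(round(duration / cfg.timestep)), 1)
        p = MDParams(timestep=cfg.timestep, temperature=cfg.temperature,
                     friction=cfg.friction, n_steps=n_steps, seed=cfg.seed,
                     ensemble="langevin")
        if cfg.mode == "downhill":
            t = run_md(start, state.model, p, stride=cfg.md_stride,
                       velocities=traj.velocities, rng=rng)
            bias_out = None
        else:
            t, bias_out = wtmetad_run(start, state.model, traj.bias, p,
                                      walls=walls, stride=cfg.md_stride,
                                      rng=rng, velocities=traj.velocities,
                                      deposit_phase=traj.deposit_phase)
            traj.bias = bias_out
            traj.deposit_phase = (traj.deposit_phase + n_steps * cfg.timestep) \
                % traj.bias.tau_deposit
        traj.unstable = t.unstable
        if not t.unstable:
            any_ok = True
        traj.positions = t.final_positions.copy()
        traj.velocities = t.final_velocities.copy()

        candidate = initial.copy(
            positions=t.final_positions.copy(), energy=None, forces=None,
            tag=f"al-iter-{state.iteration}/traj-{traj.index}",
        )
        try:
            if cfg.selector == "energy":
                selected, labelled = energy_selector(
                    candidate, state.model, gt, cfg.energy_threshold
                )
            else:
                selected = similarity_selector(
                    candidate, state.dataset, spec, cfg.similarity_threshold
                )
                labelled = gt.label(candidate) if selected else None
        except (FloatingPointError, ValueError) as exc:
            state.record(event="candidate-discarded", iteration=state.iteration,
                         traj=traj.index, reason=str(exc))
            traj.n += 1
            continue
        if selected and labelled is not None and cfg.max_label_above_min is not None:
            floor = min(c.energy for c in state.dataset if c.energy is not None)
            if labelled.energy - floor > cfg.max_label_above_min:
                state.record(event="discarded-high-energy",
                             iteration=state.iteration, traj=traj.index,
                             energy=labelled.energy)
                selected = False
        state.record(event="selector", iteration=state.iteration,
                     traj=traj.index, n=traj.n, selected=bool(selected),
                     unstable=bool(t.unstable))
        if selected:
            selections.append((traj, labelled))
        else:
            traj.n += 1

    if ib_per_iter:
        # the averaged bias of this iteration's runs becomes the next
        # iteration's inherited bias, selection or not
        run_biases = [t.bias for t in state.trajs if t.bias is not None]
        if run_biases:
            state.inherited_bias = average_biases(run_biases)

    if selections:
        for traj, labelled in selections:
            dataset_append_unique(state.dataset, labelled, cfg.dedup_tol)
        state.model = SurrogateModel(
            DescriptorSpec(cfg.descriptor_r_scale, cfg.descriptor_pad),
            ridge=cfg.ridge, energy_clip=cfg.energy_clip,
        ).train(state.dataset)
        if cfg.mode == "wtmetad-ib" and not cfg.ib_restart_each_iteration:
            state.inherited_bias = average_biases(
                [t.bias for t in state.trajs if t.bias is not None]
            )
        restart = (state.trajs if cfg.restart_scope == "all"
                   else [traj for traj, _ in selections])
        for traj in restart:
            traj.needs_restart = True
            if cfg.reset_n_on_selection:
                traj.n = 0
        state.consecutive_dead_iterations = 0
    elif not any_ok:
        state.consecutive_dead_iterations += 1
        if state.consecutive_dead_iterations >= 3:
            raise RuntimeError(
                "three consecutive iterations with every trajectory unstable "
                "and nothing selected; the surrogate cannot be stabilised "
                "from the current dataset"
            )
    else:
        state.consecutive_dead_iterations = 0

    state.iteration += 1
    return state


@dataclass
class ALResult:
    model: SurrogateModel
    dataset: Dataset
    bias_history: list[BiasPotential]
    state: ALState
    manifest: dict
    gt_calls: int = 0


def run_al(cfg: ALConfig, gt, initial: Configuration, cvs=None, walls=(),
           manifest_path=None, initial_dataset: Dataset | None = None,
           iterations_done: int = 0) -> ALResult:
    """Run the full active-learning loop and return its artefacts.

    ``initial`` seeds both the random-displacement initialisation and (mode
    dependent) the trajectory restarts; for downhill sampling it must be a
    transition-state-like structure.  ``cvs`` are required for the
    metadynamics modes.  A machine-readable manifest of seeds, thresholds
    and counts is always produced (and written to ``manifest_path`` when
    given).
    """
    cvs = list(cvs) if cvs else []
    if cfg.mode != "downhill" and not cvs:
        raise ValueError("metadynamics modes require at least one CV")
    import time as _time

    t_start = _time.perf_counter()
    counting = gt if isinstance(gt, CountingGroundTruth) else CountingGroundTruth(gt)
    root = np.random.SeedSequence(cfg.seed)
    init_rng, loop_rng = [np.random.default_rng(s) for s in root.spawn(2)]

    state = ALState(iteration=iterations_done)
    if initial_dataset is not None and len(initial_dataset):
        for c in initial_dataset:
            dataset_append_unique(state.dataset, c, cfg.dedup_tol)
    else:
        for c in random_displace(initial, cfg.init_count, cfg.init_magnitude,
                                 rng=init_rng):
            dataset_append_unique(state.dataset, counting.label(c),
                                  cfg.dedup_tol)
    if state.dataset.labelled_count == 0:
        raise RuntimeError("initial labelling produced no usable data")
    state.model = SurrogateModel(
        DescriptorSpec(cfg.descriptor_r_scale, cfg.descriptor_pad),
        ridge=cfg.ridge, energy_clip=cfg.energy_clip,
    ).train(state.dataset)
    state.trajs = [_TrajState(index=j) for j in range(cfg.n_parallel)]
    if cfg.mode == "wtmetad-ib":
        state.inherited_bias = cfg.make_bias(cvs)

    bias_history: list[BiasPotential] = []
    while state.iteration < cfg.max_iterations:
        if all(md_duration(t.n) >= cfg.max_md_time for t in state.trajs):
            break
        al_iteration(state, cfg, counting, initial, cvs, walls=walls,
                     rng=loop_rng)
        if cfg.mode == "wtmetad-ib" and state.inherited_bias is not None:
            bias_history.append(state.inherited_bias)

    manifest = {
        "mode": cfg.mode,
        "seed": cfg.seed,
        "selector": cfg.selector,
        "energy_threshold": cfg.energy_threshold,
        "similarity_threshold": cfg.similarity_threshold,
        "temperature": cfg.temperature,
        "n_parallel": cfg.n_parallel,
        "iterations": state.iteration,
        "dataset_size": len(state.dataset),
        "labelled_count": state.dataset.labelled_count,
        "ground_truth_calls": counting.calls,
        "n_bias_snapshots": len(bias_history),
        "wall_clock_s": round(_time.perf_counter() - t_start, 3),
        "config": {k: (v if not isinstance(v, (np.ndarray, tuple)) else list(v))
                   for k, v in asdict(cfg).items()},
    }
    if manifest_path:
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)
    return ALResult(model=state.model, dataset=state.dataset,
                    bias_history=bias_history, state=state,
                    manifest=manifest, gt_calls=counting.calls)
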