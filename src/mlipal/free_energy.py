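"""Free-energy estimation and trajectory post-processing.

Three estimators are provided:

* umbrella sampling (harmonic windows along a CV) combined by the
  self-consistent weighted histogram analysis method (WHAM);
* the well-tempered bias relation F(s) = −γ/(γ−1)·V_bias(s) (see
  :func:`mlipal.metadynamics.fes_from_bias`);
* final-bias reweighting of a metadynamics trajectory: every sampled CV
  value is weighted by exp(+V_final(s)/kBT) and the weighted density is
  smoothed by Gaussian kernel density estimation.

Plus barrier extraction from a free-energy profile and predicate-based
classification of trajectory ensembles (e.g. counting runs that ever reach
a solvent-separated-ion-pair-like geometry).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .configurations import Configuration
from .cvs import CollectiveVariable
from .dynamics import CompositePotential, MDParams, Trajectory, run_md
from .fes import FESEstimate
from .metadynamics import BiasPotential, wtmetad_run
from .units import KB

__all__ = [
    "FESEstimate", "UmbrellaWindow", "HarmonicRestraint", "run_umbrella",
    "wham", "reweight_fes", "production_wtmetad", "barrier",
    "classify_fraction", "DistancePredicate", "boltzmann_samples",
]


class HarmonicRestraint:
    """Umbrella bias w(ξ) = ½ k (ξ − center)² acting through a CV.

    The ½-convention is deliberate and recorded in run metadata as
    ``harmonic_half: true`` so that quoted force constants are unambiguous.
    """

    def __init__(self, cv: CollectiveVariable, center: float, k: float):
        if k <= 0:
            raise ValueError("force constant must be > 0")
        self.cv = cv
        self.center = float(center)
        self.k = float(k)

    def bias(self, xi):
        return 0.5 * self.k * (np.asarray(xi) - self.center) ** 2

    def energy_forces(self, c: Configuration):
        s, g = self.cv.value_gradient(c)
        d = s - self.center
        return 0.5 * self.k * d * d, -self.k * d * g


@dataclass
class UmbrellaWindow:
    """One umbrella window: center, force constant and its CV samples."""

    center: float                 # CV units
    k: float                      # eV per (CV unit)²
    samples: np.ndarray           # post-equilibration CV series
    temperature: float = 300.0    # K

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError(
                f"window at {self.center} has no post-equilibration samples"
            )
        if self.k <= 0:
            raise ValueError("force constant must be > 0")

    def bias(self, xi):
        return 0.5 * self.k * (np.asarray(xi) - self.center) ** 2


def boltzmann_samples(energy_fn, grid: np.ndarray, T: float, n: int,
                      rng: np.random.Generator, bias_fn=None) -> np.ndarray:
    """Exact 1D Boltzmann draws by inverse-CDF sampling on a dense grid.

    ``energy_fn`` maps CV values to energies (eV); ``bias_fn``, when given,
    is added (e.g. an umbrella window restraint), so the draws follow the
    *biased* density exp(−β(V+w)).  Used as an independent sampling oracle
    for the histogram-based estimators.
    """
    grid = np.asarray(grid, dtype=float)
    beta = 1.0 / (KB * T)
    e = np.asarray(energy_fn(grid), dtype=float)
    if bias_fn is not None:
        e = e + np.asarray(bias_fn(grid), dtype=float)
    logp = -beta * (e - e.min())
    p = np.exp(logp)
    cdf = np.cumsum(p)
    cdf /= cdf[-1]
    u = rng.random(n)
    return np.interp(u, cdf, grid)


def histogram_overlap(a: UmbrellaWindow, b: UmbrellaWindow,
                      bins: int = 50) -> float:
    """Fraction of shared probability mass between two windows' histograms."""
    lo = min(a.samples.min(), b.samples.min())
    hi = max(a.samples.max(), b.samples.max())
    ha, _ = np.histogram(a.samples, bins=bins, range=(lo, hi), density=False)
    hb, _ = np.histogram(b.samples, bins=bins, range=(lo, hi), density=False)
    pa = ha / ha.sum()
    pb = hb / hb.sum()
    return float(np.minimum(pa, pb).sum())


def run_umbrella(
    model,
    cv: CollectiveVariable,
    centers,
    k: float,
    T: float,
    time_per_window: float,
    equil: float,
    p: MDParams | None = None,
    start: Configuration | None = None,
    walls=(),
    stride: int = 5,
    seed: int = 0,
) -> list[UmbrellaWindow]:
    """Biased Langevin run per window; samples recorded after ``equil`` fs.

    Windows are visited in order and each starts from the previous window's
    final frame, which keeps the walker near the new restraint center.
    """
    centers = list(centers)
    if sorted(centers) != centers and sorted(centers, reverse=True) != centers:
        raise ValueError("window centers must be sorted")
    if not 0 <= equil < time_per_window:
        raise ValueError("need 0 <= equil < time_per_window")
    if p is None:
        p = MDParams(temperature=T)
    if start is None:
        raise ValueError("an initial configuration is required")
    rng = np.random.default_rng(seed)
    n_steps = max(int(round(time_per_window / p.timestep)), 1)
    n_equil_frames = int(round(equil / p.timestep)) // stride
    windows = []
    current = start
    for c0 in centers:
        restraint = HarmonicRestraint(cv, c0, k)
        pot = CompositePotential(model, walls=[restraint, *walls])
        params = MDParams(timestep=p.timestep, temperature=T,
                          friction=p.friction, n_steps=n_steps,
                          seed=seed, ensemble="langevin")
        traj = run_md(current, pot, params, stride=stride, cvs=[cv], rng=rng)
        series = traj.cv_series[cv.name][1:]  # drop the t=0 frame
        windows.append(UmbrellaWindow(center=c0, k=k,
                                      samples=series[n_equil_frames:],
                                      temperature=T))
        current = current.copy(positions=traj.final_positions,
                               energy=None, forces=None)
    return windows


def wham(
    windows: list[UmbrellaWindow],
    T: float,
    bins: int = 200,
    tol: float = 1e-7,
    max_iter: int = 100000,
    grid_range: tuple[float, float] | None = None,
) -> FESEstimate:
    """Self-consistent WHAM over umbrella windows.

    Iterates the coupled equations

        P(ξ) ∝ Σ_i n_i(ξ) / Σ_j N_j exp(β(F_j − w_j(ξ)))
        F_j  = −kBT ln Σ_ξ P(ξ) exp(−β w_j(ξ))

    until the largest window free-energy change drops below ``tol`` (eV),
    then reports F(ξ) = −kBT ln P(ξ), min-shifted.  The grid spans the
    sampled CV range padded by 2% unless ``grid_range`` is given.
    """
    if not windows:
        raise ValueError("need at least one window")
    beta = 1.0 / (KB * T)
    all_s = np.concatenate([w.samples for w in windows])
    if grid_range is None:
        lo, hi = all_s.min(), all_s.max()
        pad = 0.02 * (hi - lo if hi > lo else 1.0)
        lo, hi = lo - pad, hi + pad
    else:
        lo, hi = grid_range
    edges = np.linspace(lo, hi, bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    counts = np.array([np.histogram(w.samples, bins=edges)[0] for w in windows])
    n_tot = counts.sum(axis=0).astype(float)          # per-bin counts
    N = counts.sum(axis=1).astype(float)              # per-window totals
    w_bias = np.array([w.bias(mids) for w in windows])  # (W, bins)
    expw = np.exp(-beta * w_bias)

    F = np.zeros(len(windows))
    converged = False
    for _ in range(max_iter):
        denom = (N[:, None] * np.exp(beta * F)[:, None] * expw).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            P = np.where(denom > 0, n_tot / denom, 0.0)
        Z = P.sum()
        if Z > 0:
            P /= Z
        newF = np.empty_like(F)
        for j in range(len(windows)):
            s = (P * expw[j]).sum()
            newF[j] = -np.log(max(s, 1e-300)) / beta
        newF -= newF[0]
        if np.max(np.abs(newF - F)) < tol:
            F = newF
            converged = True
            break
        F = newF

    with np.errstate(divide="ignore"):
        free = np.where(P > 0, -np.log(np.where(P > 0, P, 1.0)) / beta, np.inf)
    return FESEstimate(grid=mids, F=free,
                       metadata={"method": "wham", "T": T,
                                 "converged": converged,
                                 "harmonic_half": True,
                                 "n_windows": len(windows)})


def reweight_fes(
    traj_or_samples,
    final_bias: BiasPotential,
    T: float,
    bandwidth: float,
    grid: np.ndarray,
) -> FESEstimate:
    """Final-bias reweighting with kernel density estimation.

    Each CV sample s_t gets weight w_t ∝ exp(+V_final(s_t)/kBT) (the final
    bias is what flattened the sampling; exponentiating it back restores the
    unbiased measure).  The weighted density is smoothed with a Gaussian
    kernel of the given ``bandwidth`` (CV units) and converted to
    F = −kBT ln p, min-shifted.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    if isinstance(traj_or_samples, Trajectory):
        if not traj_or_samples.cv_series:
            raise ValueError("trajectory carries no CV series")
        name = final_bias.cvs[0].name if final_bias.cvs else \
            next(iter(traj_or_samples.cv_series))
        samples = traj_or_samples.cv_series[name]
    else:
        samples = np.asarray(traj_or_samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least two CV samples")
    grid = np.asarray(grid, dtype=float)
    beta = 1.0 / (KB * T)
    v = final_bias.energy_grid(samples)
    logw = beta * v
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()

    dens = np.zeros_like(grid)
    chunk = 20000
    norm = 1.0 / (np.sqrt(2.0 * np.pi) * bandwidth)
    for i in range(0, samples.size, chunk):
        z = (grid[:, None] - samples[None, i : i + chunk]) / bandwidth
        dens += (np.exp(-0.5 * z * z) @ w[i : i + chunk]) * norm
    with np.errstate(divide="ignore"):
        F = np.where(dens > 0, -np.log(np.where(dens > 0, dens, 1.0)) / beta,
                     np.inf)
    return FESEstimate(grid=grid, F=F,
                       metadata={"method": "reweight-kde", "T": T,
                                 "bandwidth": bandwidth,
                                 "n_samples": int(samples.size)})


def production_wtmetad(
    model,
    cv: CollectiveVariable,
    bias_params: dict,
    T: float,
    time: float,
    reps: int,
    start: Configuration,
    initial_bias: BiasPotential | None = None,
    seeds=None,
    timestep: float = 0.5,
    friction: float | None = None,
    walls=(),
    stride: int = 10,
    grid: np.ndarray | None = None,
    bandwidth: float = 0.02,
) -> FESEstimate:
    """Independent well-tempered metadynamics replicas → mean FES ± σ.

    Each replica starts from the same configuration with independently
    drawn velocities; supplying ``initial_bias`` realises a warm-started
    (inherited-bias) production run.  Per-replica surfaces come from
    final-bias reweighting; the mean and across-replica standard deviation
    are reported.  Unstable replicas are dropped (an error is raised if
    more than half are lost).
    """
    from .dynamics import DEFAULT_FRICTION

    if reps < 1:
        raise ValueError("reps must be >= 1")
    if seeds is None:
        seeds = list(range(reps))
    if friction is None:
        friction = DEFAULT_FRICTION
    if grid is None:
        grid = np.linspace(-2.0, 2.0, 401)
    n_steps = max(int(round(time / timestep)), 1)
    profiles = []
    n_unstable = 0
    biases = []
    for seed in seeds[:reps]:
        rng = np.random.default_rng(seed)
        if initial_bias is not None:
            b = initial_bias.spawn()
            for key, val in bias_params.items():
                setattr(b, key, float(val) if np.isscalar(val) else val)
        else:
            b = BiasPotential([cv], **bias_params)
        p = MDParams(timestep=timestep, temperature=T, friction=friction,
                     n_steps=n_steps, seed=int(seed), ensemble="langevin")
        traj, b_out = wtmetad_run(start, model, b, p, walls=walls,
                                  stride=stride, rng=rng)
        if traj.unstable:
            n_unstable += 1
            continue
        fes = reweight_fes(traj, b_out, T, bandwidth, grid)
        profiles.append(fes.F)
        biases.append(b_out)
    if n_unstable > reps / 2:
        raise RuntimeError(f"{n_unstable} of {reps} replicas were unstable")
    P = np.array(profiles)
    finite = np.isfinite(P).all(axis=0)
    mean = np.where(finite, P.mean(axis=0), np.inf)
    sigma = np.where(finite, P.std(axis=0, ddof=1) if len(P) > 1 else 0.0, 0.0)
    return FESEstimate(grid=np.asarray(grid, dtype=float), F=mean, sigma=sigma,
                       metadata={"method": "wtmetad-production", "T": T,
                                 "reps": len(profiles),
                                 "n_unstable": n_unstable,
                                 "biases": biases})


def barrier(f: FESEstimate, basin_a: tuple[float, float],
            basin_b: tuple[float, float]) -> tuple[float, float]:
    """Forward free-energy barrier from basin_a to basin_b.

    ΔG = max F on the segment between the two basin minima minus min F in
    ``basin_a``; also returns the CV location of the maximum (the TS).
    """
    g, F = f.grid, f.F
    in_a = (g >= basin_a[0]) & (g <= basin_a[1]) & np.isfinite(F)
    in_b = (g >= basin_b[0]) & (g <= basin_b[1]) & np.isfinite(F)
    if not in_a.any() or not in_b.any():
        raise ValueError("basin intervals contain no finite grid points")
    ia = np.flatnonzero(in_a)[np.argmin(F[in_a])]
    ib = np.flatnonzero(in_b)[np.argmin(F[in_b])]
    lo, hi = sorted((ia, ib))
    if hi - lo < 2:
        raise ValueError("no interior points between the basin minima")
    seg = F[lo + 1 : hi]
    its = lo + 1 + int(np.nanargmax(np.where(np.isfinite(seg), seg, -np.inf)))
    return float(F[its] - F[ia]), float(g[its])


class DistancePredicate:
    """Conjunction of interatomic-distance threshold conditions.

    ``conditions`` is a list of ``(i, j, op, threshold)`` with ``op`` one of
    ``">"`` or ``"<"``; the predicate holds on a frame when every condition
    does.  This is the geometric test used, e.g., to flag
    solvent-separated-ion-pair-like frames (both key distances beyond their
    thresholds).
    """

    def __init__(self, conditions):
        self.conditions = []
        for i, j, op, thr in conditions:
            if op not in (">", "<"):
                raise ValueError(f"unsupported comparison {op!r}")
            self.conditions.append((int(i), int(j), op, float(thr)))

    def on_frame(self, c: Configuration) -> bool:
        for i, j, op, thr in self.conditions:
            r = float(np.linalg.norm(c.positions[i] - c.positions[j]))
            if (op == ">" and not r > thr) or (op == "<" and not r < thr):
                return False
        return True

    def on_trajectory(self, t: Trajectory) -> bool:
        return any(self.on_frame(fr) for fr in t.frames)


def classify_fraction(trajs: list[Trajectory], predicate) -> dict:
    """Fraction of trajectories with ≥ 1 frame satisfying the predicate.

    Returns the fraction together with its Wilson-score 95% confidence
    interval.
    """
    if not trajs:
        raise ValueError("need at least one trajectory")
    hits = sum(1 for t in trajs if predicate.on_trajectory(t))
    n = len(trajs)
    p = hits / n
    z = 1.959963984540054
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return {"fraction": p, "count": hits, "n": n,
            "ci95": (max(center - half, 0.0), min(center + half, 1.0))}
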