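"""Well-tempered metadynamics: hills, bias evaluation, inherited-bias algebra.

A bias potential is a sum of Gaussian hills on CV space,

    V(s) = Σ_k h_k · exp(−Σ_i (s_i − c_ki)² / (2 σ_ki²)),

with well-tempered height decay h = h0·exp(−V(s)/(kB (γ−1) T)) at each
deposition.  The inherited-bias scheme used between active-learning
iterations carries the previous iteration's bias forward unchanged and
1/n-averages only the hills newly deposited by the n parallel runs; the
carried-forward hills are shared objects, which is how the averaging
recognises them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .configurations import Configuration, Dataset
from .dynamics import CompositePotential, MDParams, Trajectory, run_md
from .fes import FESEstimate
from .units import KB


@dataclass(frozen=True)
class Hill:
    """One deposited Gaussian: per-CV center and width, height, timestamp."""

    centers: tuple        # per-CV, CV units
    widths: tuple         # per-CV σ, CV units
    height: float         # eV
    time: float = 0.0     # fs since the start of the depositing run

    def __post_init__(self):
        if any(w <= 0 for w in self.widths):
            raise ValueError("hill widths must be > 0")
        if self.height < 0:
            raise ValueError("hill height must be >= 0")


class BiasPotential:
    """Sum of Gaussian hills with well-tempered bookkeeping.

    Parameters: ``cvs`` — ordered collective variables the bias acts on;
    ``h0`` — initial hill height (eV); ``gamma`` — bias factor γ > 1;
    ``T`` — temperature (K) entering the tempering rule; ``tau_deposit`` —
    deposition period (fs); ``sigma`` — per-CV hill width.
    """

    def __init__(self, cvs, h0: float, gamma: float, T: float,
                 tau_deposit: float, sigma):
        if gamma <= 1:
            raise ValueError("bias factor gamma must be > 1")
        if h0 < 0 or tau_deposit <= 0:
            raise ValueError("h0 must be >= 0 and tau_deposit > 0")
        self.cvs = list(cvs)
        self.h0 = float(h0)
        self.gamma = float(gamma)
        self.T = float(T)
        self.tau_deposit = float(tau_deposit)
        sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
        if sigma.size == 1 and len(self.cvs) > 1:
            sigma = np.repeat(sigma, len(self.cvs))
        if sigma.size != max(len(self.cvs), 1):
            raise ValueError("one sigma per CV required")
        self.sigma = sigma
        self.hills: list[Hill] = []
        self._cache = None

    # ---------------- construction helpers ----------------

    def spawn(self) -> "BiasPotential":
        """New bias sharing parameters and the current hill objects.

        Used to extend a bias during a run without mutating the input: the
        shared (inherited) hills keep their identity, which the
        inherited-bias averaging relies on.
        """
        b = BiasPotential(self.cvs, self.h0, self.gamma, self.T,
                          self.tau_deposit, self.sigma.copy())
        b.hills = list(self.hills)
        return b

    @property
    def n_hills(self) -> int:
        return len(self.hills)

    def add_hill(self, hill: Hill) -> None:
        self.hills.append(hill)
        self._cache = None

    def deposit(self, s, time: float = 0.0) -> Hill:
        """Deposit a well-tempered hill at CV point ``s`` and return it."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        h = self.next_height(s)
        hill = Hill(centers=tuple(s), widths=tuple(self.sigma),
                    height=h, time=time)
        self.add_hill(hill)
        return hill

    # ---------------- evaluation ----------------

    def _arrays(self):
        if self._cache is None:
            if self.hills:
                C = np.array([h.centers for h in self.hills])
                W = np.array([h.widths for h in self.hills])
                H = np.array([h.height for h in self.hills])
            else:
                d = max(len(self.cvs), 1)
                C = np.empty((0, d))
                W = np.empty((0, d))
                H = np.empty(0)
            self._cache = (C, W, H)
        return self._cache

    def energy(self, s) -> float:
        """V_bias at CV point ``s`` (eV); ≥ 0, zero with no hills."""
        C, W, H = self._arrays()
        if H.size == 0:
            return 0.0
        s = np.atleast_1d(np.asarray(s, dtype=float))
        z = (s[None, :] - C) / W
        return float(H @ np.exp(-0.5 * (z * z).sum(axis=1)))

    def energy_grid(self, grid: np.ndarray) -> np.ndarray:
        """Vectorised ``energy`` over a (M,) or (M, n_cv) grid."""
        C, W, H = self._arrays()
        grid = np.asarray(grid, dtype=float)
        pts = grid[:, None] if grid.ndim == 1 else grid
        if H.size == 0:
            return np.zeros(len(pts))
        z = (pts[:, None, :] - C[None, :, :]) / W[None, :, :]
        return np.exp(-0.5 * (z * z).sum(axis=2)) @ H

    def gradient(self, s) -> np.ndarray:
        """∂V_bias/∂s, one scalar per CV."""
        return self.energy_gradient(s)[1]

    def energy_gradient(self, s) -> tuple[float, np.ndarray]:
        """V_bias and ∂V_bias/∂s in one pass (shared exponentials)."""
        C, W, H = self._arrays()
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if H.size == 0:
            return 0.0, np.zeros_like(s)
        d = s[None, :] - C
        z = d / W
        g = H * np.exp(-0.5 * (z * z).sum(axis=1))
        return float(g.sum()), (g[:, None] * (-d / (W * W))).sum(axis=0)

    def next_height(self, s) -> float:
        """Well-tempered height h0·exp(−V(s)/(kB (γ−1) T)) of the next hill."""
        v = self.energy(s)
        return self.h0 * np.exp(-v / (KB * (self.gamma - 1.0) * self.T))


def wtmetad_run(
    start: Configuration,
    model,
    b: BiasPotential,
    p: MDParams,
    walls=(),
    stride: int = 1,
    rng: np.random.Generator | None = None,
    velocities: np.ndarray | None = None,
    deposit_phase: float = 0.0,
) -> tuple[Trajectory, BiasPotential]:
    """One well-tempered metadynamics run of ``p.n_steps`` steps.

    Wraps :func:`mlipal.dynamics.run_md` in deposition-period segments: a
    hill is dropped at the walker's current CV point every ``tau_deposit``
    fs, with the tempered height evaluated on the full bias including any
    inherited hills.  ``deposit_phase`` (fs) is the time already elapsed
    since the last deposition when continuing a persisted trajectory.

    Returns the concatenated trajectory and the extended bias (the input
    bias is not mutated; its hill objects are shared).
    """
    if rng is None:
        rng = np.random.default_rng(p.seed)
    bias = b.spawn()
    composite = CompositePotential(model, bias=bias, walls=walls)
    dt = p.timestep
    steps_per_dep = max(int(round(b.tau_deposit / dt)), 1)
    phase_steps = int(round(deposit_phase / dt)) % steps_per_dep

    remaining = p.n_steps
    done = 0
    segs: list[Trajectory] = []
    v = velocities
    x_start = start
    while remaining > 0:
        upcoming = steps_per_dep - phase_steps
        seg_steps = min(upcoming, remaining)
        sp = MDParams(timestep=dt, temperature=p.temperature,
                      friction=p.friction, n_steps=seg_steps, seed=p.seed,
                      ensemble=p.ensemble)
        traj = run_md(x_start, composite, sp, stride=stride,
                      velocities=v, rng=rng)
        segs.append(traj)
        if traj.unstable:
            break
        x_start = x_start.copy(positions=traj.final_positions,
                               energy=None, forces=None)
        v = traj.final_velocities
        done += seg_steps
        remaining -= seg_steps
        phase_steps += seg_steps
        if phase_steps >= steps_per_dep:
            phase_steps = 0
            s = np.array([cv.value(x_start) for cv in bias.cvs])
            bias.deposit(s, time=done * dt)

    return _concat(segs, stride), bias


def _concat(segs: list[Trajectory], stride: int) -> Trajectory:
    if len(segs) == 1:
        return segs[0]
    frames = list(segs[0].frames)
    vels = list(segs[0].velocities)
    times = [segs[0].times]
    cv_series = {k: [v] for k, v in segs[0].cv_series.items()}
    bias_series = [segs[0].bias_series]
    offset = segs[0].times[-1] if len(segs[0].times) else 0.0
    for seg in segs[1:]:
        frames.extend(seg.frames[1:])
        vels.extend(seg.velocities[1:])
        times.append(seg.times[1:] + offset)
        offset += seg.times[-1] if len(seg.times) else 0.0
        for k in cv_series:
            cv_series[k].append(seg.cv_series[k][1:])
        bias_series.append(seg.bias_series[1:])
    last = segs[-1]
    return Trajectory(
        frames=frames,
        velocities=vels,
        times=np.concatenate(times),
        cv_series={k: np.concatenate(v) for k, v in cv_series.items()},
        bias_series=np.concatenate(bias_series),
        unstable=last.unstable,
        params=last.params,
        final_positions=last.final_positions,
        final_velocities=last.final_velocities,
    )


def average_biases(runs: list[BiasPotential]) -> BiasPotential:
    """Inherited-bias averaging across ``n`` parallel runs.

    The hills shared by every run (the inherited prefix, detected by object
    identity) enter once at full height — they were already averaged in the
    iteration that produced them.  Every other (newly deposited) hill
    enters with its height scaled by 1/n.  The result is the initial bias
    for all trajectories of the next active-learning iteration.
    """
    if not runs:
        raise ValueError("need at least one bias")
    ref = runs[0]
    for b in runs[1:]:
        if len(b.cvs) != len(ref.cvs) or [c.name for c in b.cvs] != [
            c.name for c in ref.cvs
        ]:
            raise ValueError("all biases must share CV definitions")
        if (b.gamma, b.T, b.h0) != (ref.gamma, ref.T, ref.h0):
            raise ValueError("all biases must share gamma, T and h0")
    n = len(runs)
    prefix = 0
    min_len = min(b.n_hills for b in runs)
    while prefix < min_len and all(
        b.hills[prefix] is ref.hills[prefix] for b in runs
    ):
        prefix += 1
    out = BiasPotential(ref.cvs, ref.h0, ref.gamma, ref.T,
                        ref.tau_deposit, ref.sigma.copy())
    out.hills = list(ref.hills[:prefix])
    for b in runs:
        for h in b.hills[prefix:]:
            out.add_hill(Hill(centers=h.centers, widths=h.widths,
                              height=h.height / n, time=h.time))
    out._cache = None
    return out


def select_restart(ds: Dataset, b: BiasPotential | None, cvs=None) -> Configuration:
    """Dataset item with the lowest biased energy E_true + V_bias(s).

    CV values are computed fresh from the stored configurations; ties are
    broken by earliest insertion.  With a zero/absent bias this is simply
    the lowest-energy training point.
    """
    cvs = list(cvs) if cvs is not None else (list(b.cvs) if b else [])
    best = None
    best_e = np.inf
    for c in ds:
        if c.energy is None:
            continue
        e = c.energy
        if b is not None and b.n_hills and cvs:
            s = np.array([cv.value(c) for cv in cvs])
            e = e + b.energy(s)
        if e < best_e:
            best, best_e = c, e
    if best is None:
        raise ValueError("dataset has no energy-labelled items")
    return best


def fes_from_bias(b: BiasPotential, grid: np.ndarray) -> FESEstimate:
    """Well-tempered estimate F(s) = −γ/(γ−1)·V_bias(s), min-shifted.

    Exact in the long-time limit of well-tempered metadynamics; as γ → ∞
    the prefactor tends to 1 and the standard-metadynamics relation
    F = −V_bias is recovered.
    """
    v = b.energy_grid(np.asarray(grid, dtype=float))
    F = -(b.gamma / (b.gamma - 1.0)) * v
    return FESEstimate(grid=np.asarray(grid, dtype=float), F=F,
                       metadata={"method": "wtmetad-bias", "gamma": b.gamma,
                                 "T": b.T, "n_hills": b.n_hills})


# --------------------------------------------------------------------------
# HILLS-format I/O (PLUMED-compatible column layout).
# --------------------------------------------------------------------------

def write_hills(b: BiasPotential, path) -> None:
    """Write the hill table: time, centers, sigmas, height, biasfactor."""
    names = [cv.name for cv in b.cvs] or ["cv0"]
    cols = ["time"] + names + [f"sigma_{n}" for n in names] + ["height", "biasf"]
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(cols) + "\n")
        fh.write(f"#! SET h0 {float(b.h0)!r}\n")
        fh.write(f"#! SET temperature {float(b.T)!r}\n")
        fh.write(f"#! SET tau_deposit {float(b.tau_deposit)!r}\n")
        for h in b.hills:
            row = [h.time, *h.centers, *h.widths, h.height, b.gamma]
            fh.write(" ".join(f"{float(x)!r}" for x in row) + "\n")


def read_hills(path, cvs=None) -> BiasPotential:
    """Read a HILLS file written by :func:`write_hills`.

    ``cvs`` optionally re-attaches CV objects (required before the bias can
    drive dynamics; pure CV-space evaluation works without them).
    """
    h0 = None
    T = 300.0
    tau = 100.0
    gamma = None
    rows = []
    n_cv = None
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#!"):
                parts = line.split()
                if len(parts) >= 4 and parts[1] == "SET":
                    if parts[2] == "h0":
                        h0 = float(parts[3])
                    elif parts[2] == "temperature":
                        T = float(parts[3])
                    elif parts[2] == "tau_deposit":
                        tau = float(parts[3])
                elif parts[1] == "FIELDS":
                    n_cv = (len(parts) - 5) // 2  # minus FIELDS,time,height,biasf
                continue
            vals = line.split()
            if n_cv is None:
                n_cv = (len(vals) - 3) // 2
            if len(vals) != 3 + 2 * n_cv:
                raise ValueError(
                    f"{path}: line {ln}: expected {3 + 2 * n_cv} columns, "
                    f"got {len(vals)}"
                )
            try:
                rows.append([float(v) for v in vals])
            except ValueError:
                raise ValueError(f"{path}: line {ln}: non-numeric entry") from None
            gamma = rows[-1][-1]
    if gamma is None:
        gamma = 10.0
    heights = [r[1 + 2 * n_cv] for r in rows]
    if h0 is None:
        h0 = max(heights) if heights else 1e-2
    sigma = np.array(rows[0][1 + n_cv : 1 + 2 * n_cv]) if rows else np.ones(max(n_cv or 1, 1))
    b = BiasPotential(cvs or [], h0=h0, gamma=gamma, T=T,
                      tau_deposit=tau, sigma=sigma)
    for r in rows:
        b.add_hill(Hill(centers=tuple(r[1 : 1 + n_cv]),
                        widths=tuple(r[1 + n_cv : 1 + 2 * n_cv]),
                        height=r[1 + 2 * n_cv], time=r[0]))
    return b
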