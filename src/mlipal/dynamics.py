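"""Langevin (BAOAB) and NVE (velocity-Verlet) propagation of configurations.

The integrator acts on a composite potential: a base energy/force provider
(an analytic surface or a trained surrogate), an optional metadynamics bias
acting through collective variables, and optional restraint walls.  Hills
are never deposited here — the metadynamics module wraps :func:`run_md` in
deposition-period segments.

Velocities are carried in Å fs⁻¹; the amu/Å/eV unit system closes through
the natural time unit ``TAU0`` (see :mod:`mlipal.units`).  A Langevin
friction of "0.02 inverse natural time units" therefore corresponds to
``0.02 / TAU0`` ≈ 1.96e-3 fs⁻¹, which is the package default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .configurations import Configuration
from .units import FORCE_TO_ACC, KB, MASS_VEL2_TO_EV, TAU0

DEFAULT_FRICTION = 0.02 / TAU0  # fs⁻¹


@dataclass
class MDParams:
    timestep: float = 0.5          # fs
    temperature: float = 300.0     # K
    friction: float = DEFAULT_FRICTION  # fs⁻¹
    n_steps: int = 1000
    seed: int = 0
    ensemble: str = "langevin"     # "langevin" | "nve"

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.friction < 0 or self.temperature < 0:
            raise ValueError("friction and temperature must be >= 0")
        if self.ensemble not in ("langevin", "nve"):
            raise ValueError(f"unknown ensemble {self.ensemble!r}")


class CompositePotential:
    """base potential + optional metadynamics bias + optional walls.

    ``base`` is anything with ``energy_forces(configuration)``; ``bias`` is
    a BiasPotential (its CV list defines how bias forces map onto atoms);
    ``walls`` is a list of WallRestraint.
    """

    def __init__(self, base, bias=None, walls=()):
        self.base = base
        self.bias = bias
        self.walls = list(walls)

    def energy_forces(self, c: Configuration):
        e, f = self.base.energy_forces(c)
        f = np.asarray(f, dtype=float)
        if self.bias is not None and self.bias.cvs:
            s = np.empty(len(self.bias.cvs))
            grads = []
            for i, cv in enumerate(self.bias.cvs):
                s[i], g = cv.value_gradient(c)
                grads.append(g)
            e_b, dvds = self.bias.energy_gradient(s)
            e += e_b
            for i, g in enumerate(grads):
                f -= dvds[i] * g
        for w in self.walls:
            ew, fw = w.energy_forces(c)
            if ew != 0.0:
                e += ew
                f = f + fw
        return e, f

    def bias_energy_at(self, c: Configuration) -> float:
        if self.bias is None or not self.bias.cvs:
            return 0.0
        s = np.array([cv.value(c) for cv in self.bias.cvs])
        return float(self.bias.energy(s))


@dataclass
class Trajectory:
    """Sampled frames of one MD run plus per-frame diagnostics.

    ``frames[k].energy`` stores the full composite potential energy; the
    bias part alone is in ``bias_series``.  ``cv_series`` maps CV name to
    its sampled time series.
    """

    frames: list[Configuration]
    velocities: list[np.ndarray]
    times: np.ndarray              # fs
    cv_series: dict[str, np.ndarray] = field(default_factory=dict)
    bias_series: np.ndarray | None = None
    unstable: bool = False
    params: MDParams | None = None
    # exact end-of-run phase-space point (independent of stride), used to
    # continue a persisted trajectory
    final_positions: np.ndarray | None = None
    final_velocities: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def kinetic_energies(self) -> np.ndarray:
        out = np.empty(self.n_frames)
        for k, (c, v) in enumerate(zip(self.frames, self.velocities)):
            out[k] = 0.5 * float((c.masses[:, None] * v * v).sum()) * MASS_VEL2_TO_EV
        return out

    def potential_energies(self) -> np.ndarray:
        return np.array([c.energy for c in self.frames], dtype=float)


def init_velocities(
    c: Configuration, T: float, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Maxwell–Boltzmann velocities (Å fs⁻¹) at temperature T; frozen axes 0."""
    if rng is None:
        rng = np.random.default_rng(seed)
    if T < 0:
        raise ValueError("temperature must be >= 0")
    sigma = np.sqrt(KB * T / c.masses)[:, None] / TAU0
    v = rng.standard_normal(c.positions.shape) * sigma
    if c.frozen_axes is not None:
        v[c.frozen_axes] = 0.0
    return v


def run_md(
    start: Configuration,
    potential,
    p: MDParams,
    stride: int = 1,
    cvs: list | None = None,
    velocities: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Propagate ``start`` for ``p.n_steps`` steps, sampling every ``stride``.

    ``potential`` is anything with ``energy_forces``; wrap it in
    :class:`CompositePotential` to add bias and walls.  ``velocities``
    continues a persisted trajectory; otherwise Maxwell–Boltzmann at
    ``p.temperature``.  A non-finite energy or force truncates the run and
    sets ``Trajectory.unstable`` instead of raising — the active-learning
    loop must survive and learn from unstable potentials.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if rng is None:
        rng = np.random.default_rng(p.seed)
    if not isinstance(potential, CompositePotential):
        potential = CompositePotential(potential)
    cvs = list(cvs) if cvs else (list(potential.bias.cvs) if potential.bias else [])

    work = start.copy()
    x = work.positions
    m = work.masses[:, None]
    frozen = work.frozen_axes
    v = init_velocities(work, p.temperature, rng=rng) if velocities is None \
        else np.array(velocities, dtype=float)
    if frozen is not None:
        v[frozen] = 0.0

    dt = p.timestep
    langevin = p.ensemble == "langevin" and p.friction > 0
    if langevin:
        c1 = np.exp(-p.friction * dt)
        c2 = np.sqrt((1.0 - c1 * c1) * KB * p.temperature / work.masses)[:, None] / TAU0

    def record(e_pot):
        snap = work.copy()
        snap.energy = float(e_pot)
        frames.append(snap)
        vels.append(v.copy())
        for cv in cvs:
            cv_series[cv.name].append(cv.value(work))
        bias_series.append(potential.bias_energy_at(work))

    frames: list[Configuration] = []
    vels: list[np.ndarray] = []
    cv_series: dict[str, list] = {cv.name: [] for cv in cvs}
    bias_series: list[float] = []
    times = [0.0]

    e, f = potential.energy_forces(work)
    unstable = not (np.isfinite(e) and np.isfinite(float(np.sum(f))))
    if frozen is not None:
        f = f.copy()
        f[frozen] = 0.0
    record(e)

    half_kick = 0.5 * dt * FORCE_TO_ACC / m
    step = 0
    while step < p.n_steps and not unstable:
        v = v + half_kick * f                      # B
        x += 0.5 * dt * v                          # A
        if langevin:
            noise = rng.standard_normal(x.shape)
            v *= c1                                # O
            v += c2 * noise
            if frozen is not None:
                v[frozen] = 0.0
        x += 0.5 * dt * v                          # A
        e, f = potential.energy_forces(work)
        if not (np.isfinite(e) and np.isfinite(float(np.sum(f)))):
            unstable = True
            break
        if frozen is not None:
            f = f.copy()
            f[frozen] = 0.0
        v += half_kick * f                         # B
        if frozen is not None:
            v[frozen] = 0.0
        step += 1
        if step % stride == 0:
            record(e)
            times.append(step * dt)

    traj = Trajectory(
        frames=frames,
        velocities=vels,
        times=np.array(times[: len(frames)]),
        cv_series={k: np.array(s) for k, s in cv_series.items()},
        bias_series=np.array(bias_series),
        unstable=unstable,
        params=p,
        final_positions=x.copy(),
        final_velocities=v.copy(),
    )
    return traj


def write_cv_series(t: Trajectory, path) -> None:
    """Write a trajectory's CV and bias time series as a headed TSV."""
    names = sorted(t.cv_series)
    with open(path, "w") as fh:
        fh.write("time_fs\t" + "\t".join(names) + "\tbias_eV\n")
        for k in range(t.n_frames):
            row = [t.times[k]] + [t.cv_series[n][k] for n in names]
            row.append(t.bias_series[k] if t.bias_series is not None else 0.0)
            fh.write("\t".join(f"{float(x)!r}" for x in row) + "\n")


def nve_drift(t: Trajectory) -> float:
    """Least-squares slope of total energy vs time, in eV ps⁻¹.

    Requires an NVE trajectory with recorded velocities; the total energy
    is the sampled potential plus kinetic energy.
    """
    if t.params is not None and t.params.ensemble != "nve":
        raise ValueError("nve_drift requires an NVE trajectory")
    if not t.velocities:
        raise ValueError("trajectory carries no velocities")
    e_tot = t.potential_energies() + t.kinetic_energies()
    times_ps = t.times / 1000.0
    if np.ptp(e_tot) == 0.0:
        return 0.0
    slope = np.polyfit(times_ps, e_tot, 1)[0]
    return float(slope)
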