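"""Analytic ground-truth potentials and brute-force landscape helpers.

These surfaces play the role an electronic-structure code plays in a real
active-learning campaign: they label configurations with energies and
forces.  All act on designated coordinates of ordinary 3D configurations
(the remaining coordinates are masked by ``frozen_axes``), so the full
dynamics/metadynamics/free-energy stack runs on them unmodified.

Three fixtures are provided:

* :class:`DoubleWell1D` — a quartic double well on one atom's x coordinate;
  the minimal two-basin reactive profile.
* :class:`MuellerBrown2D` — the standard four-Gaussian multi-basin test
  surface for enhanced-sampling methods, on one atom's (x, y).
* :class:`TriatomicExchange` — a Morse-based A–B + B–C bond-exchange system
  whose natural collective variable is the bond-length difference
  r_AB − r_BC, mimicking an S\\ :sub:`N`\\ 2-like topology.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .configurations import Configuration


class GroundTruth:
    """Contract for an energy/force oracle.

    Subclasses implement :meth:`evaluate` returning ``(energy, forces)`` in
    eV and eV Å⁻¹, with forces equal to the negative analytic gradient.
    """

    name = "ground-truth"
    n_atoms: int | None = None  # None = any atom count

    def evaluate(self, c: Configuration) -> tuple[float, np.ndarray]:
        raise NotImplementedError

    def energy_forces(self, c: Configuration) -> tuple[float, np.ndarray]:
        """Alias used by the dynamics composite-potential machinery."""
        if self.n_atoms is not None and c.n_atoms != self.n_atoms:
            raise ValueError(
                f"{self.name} expects {self.n_atoms} atoms, got {c.n_atoms}"
            )
        return self.evaluate(c)

    def label(self, c: Configuration) -> Configuration:
        """Return a copy of ``c`` carrying this surface's energy/forces."""
        e, f = self.energy_forces(c)
        out = c.copy()
        out.energy = float(e)
        out.forces = f
        return out

    def make_configuration(self, coords) -> Configuration:
        """Build a configuration of this surface's native layout."""
        raise NotImplementedError


class DoubleWell1D(GroundTruth):
    """V(x) = h_b ((x/w)² − 1)² on atom 0's x coordinate.

    Minima at x = ±w with V = 0; barrier V(0) = h_b.  The y and z axes are
    frozen.
    """

    name = "double-well-1d"
    n_atoms = 1

    def __init__(self, barrier_height: float = 0.2, half_width: float = 1.0):
        self.barrier_height = float(barrier_height)
        self.half_width = float(half_width)

    def evaluate(self, c: Configuration):
        x = c.positions[0, 0]
        u = (x / self.half_width) ** 2 - 1.0
        e = self.barrier_height * u * u
        dedx = 4.0 * self.barrier_height * u * x / self.half_width**2
        f = np.zeros_like(c.positions)
        f[0, 0] = -dedx
        return e, f

    def make_configuration(self, coords=(-1.0,)) -> Configuration:
        frozen = np.array([[False, True, True]])
        return Configuration(
            positions=[[float(coords[0]), 0.0, 0.0]],
            elements=["C"],
            frozen_axes=frozen,
            tag="double-well",
        )


# Standard Müller–Brown constants (raw units).
_MB_A = np.array([-200.0, -100.0, -170.0, 15.0])
_MB_a = np.array([-1.0, -1.0, -6.5, 0.7])
_MB_b = np.array([0.0, 0.0, 11.0, 0.6])
_MB_c = np.array([-10.0, -10.0, -6.5, 0.7])
_MB_x0 = np.array([1.0, 0.0, -0.5, -1.0])
_MB_y0 = np.array([0.0, 0.5, 1.5, 1.0])


class MuellerBrown2D(GroundTruth):
    """The Müller–Brown four-term exponential surface on atom 0's (x, y).

    Raw units are arbitrary; ``scale`` (default 5e-3 eV per raw unit) maps
    the landscape into a thermally meaningful range at ~300 K, so the
    barrier between the two deepest basins is of order 0.5 eV.  The z axis
    is frozen.
    """

    name = "mueller-brown-2d"
    n_atoms = 1

    def __init__(self, scale: float = 5e-3):
        self.scale = float(scale)

    def raw_energy_grad(self, x: float, y: float):
        dx = x - _MB_x0
        dy = y - _MB_y0
        terms = _MB_A * np.exp(_MB_a * dx**2 + _MB_b * dx * dy + _MB_c * dy**2)
        e = terms.sum()
        dedx = (terms * (2.0 * _MB_a * dx + _MB_b * dy)).sum()
        dedy = (terms * (_MB_b * dx + 2.0 * _MB_c * dy)).sum()
        return e, dedx, dedy

    def evaluate(self, c: Configuration):
        x, y = c.positions[0, 0], c.positions[0, 1]
        e, dedx, dedy = self.raw_energy_grad(x, y)
        f = np.zeros_like(c.positions)
        f[0, 0] = -self.scale * dedx
        f[0, 1] = -self.scale * dedy
        return self.scale * e, f

    def make_configuration(self, coords=(-0.558, 1.442)) -> Configuration:
        frozen = np.array([[False, False, True]])
        return Configuration(
            positions=[[float(coords[0]), float(coords[1]), 0.0]],
            elements=["C"],
            frozen_axes=frozen,
            tag="mueller-brown",
        )


class TriatomicExchange(GroundTruth):
    """Morse-based collinear-free A–B–C bond-exchange surface.

    V = M(r_AB) + M(r_BC) + C_rep exp(−α[(r_AB − r0)² + (r_BC − r0)²]) with
    M(r) = D (1 − exp(−a (r − r0)))².  The two basins (A–B bonded vs B–C
    bonded) are exactly symmetric and the natural CV is the distance
    difference r_AB − r_BC.

    Two off-diagonal basins only exist when the both-bonds-formed point
    (r0, r0) is destabilised strongly enough, which requires
    α·C_rep > D·a²; the defaults (D = 1 eV, a = 1.5 Å⁻¹, C_rep = 2 eV,
    α = 2 Å⁻²) satisfy this with a ≈ 0.32 eV exchange barrier and basins
    near r_AB − r_BC = ±1.29 Å.
    """

    name = "triatomic-exchange"
    n_atoms = 3

    def __init__(
        self,
        D: float = 1.0,
        a: float = 1.5,
        r0: float = 1.6,
        C_rep: float = 2.0,
        alpha: float = 2.0,
    ):
        self.D, self.a, self.r0 = float(D), float(a), float(r0)
        self.C_rep, self.alpha = float(C_rep), float(alpha)

    def _morse(self, r):
        ex = np.exp(-self.a * (r - self.r0))
        e = self.D * (1.0 - ex) ** 2
        dedr = 2.0 * self.D * (1.0 - ex) * self.a * ex
        return e, dedr

    def evaluate(self, c: Configuration):
        p = c.positions
        v_ab = p[0] - p[1]
        v_bc = p[2] - p[1]
        r_ab = np.linalg.norm(v_ab)
        r_bc = np.linalg.norm(v_bc)
        e1, de1 = self._morse(r_ab)
        e2, de2 = self._morse(r_bc)
        g = np.exp(
            -self.alpha * ((r_ab - self.r0) ** 2 + (r_bc - self.r0) ** 2)
        )
        e_rep = self.C_rep * g
        # dV/dr_ab and dV/dr_bc
        dab = de1 - 2.0 * self.alpha * (r_ab - self.r0) * e_rep
        dbc = de2 - 2.0 * self.alpha * (r_bc - self.r0) * e_rep
        u_ab = v_ab / r_ab
        u_bc = v_bc / r_bc
        f = np.zeros_like(p)
        f[0] = -dab * u_ab
        f[2] = -dbc * u_bc
        f[1] = dab * u_ab + dbc * u_bc
        return e1 + e2 + e_rep, f

    def make_configuration(self, r_ab: float | None = None, r_bc: float = 3.2,
                           collinear_frozen: bool = False):
        """Collinear A–B–C start with given bond lengths (Å).

        ``collinear_frozen=True`` freezes everything except the x
        coordinates of A and C (with B pinned at the origin), giving a 2D
        template for grid-based landscape searches.
        """
        if r_ab is None:
            r_ab = self.r0
        frozen = None
        if collinear_frozen:
            frozen = np.array([[False, True, True],
                               [True, True, True],
                               [False, True, True]])
        return Configuration(
            positions=[[-float(r_ab), 0.0, 0.0], [0.0, 0.0, 0.0],
                       [float(r_bc), 0.0, 0.0]],
            elements=["C", "C", "C"],
            frozen_axes=frozen,
            tag="triatomic",
        )


# --------------------------------------------------------------------------
# Brute-force landscape helpers (test oracles).
# --------------------------------------------------------------------------

def _active_coords(gt: GroundTruth, c: Configuration):
    """Indices of mobile coordinates of ``c`` (flat (N*3,) view)."""
    if c.frozen_axes is not None:
        return np.flatnonzero(~c.frozen_axes.ravel())
    return np.arange(c.positions.size)


def _set_active(template: Configuration, active, x) -> None:
    flat = template.positions.ravel().copy()
    flat[active] = x
    template.positions[:] = flat.reshape(-1, 3)


def _energy_of(gt: GroundTruth, template: Configuration, active, x):
    _set_active(template, active, x)
    e, _ = gt.energy_forces(template)
    return e


def _energy_grad_of(gt: GroundTruth, template: Configuration, active, x):
    _set_active(template, active, x)
    e, f = gt.energy_forces(template)
    return e, -f.ravel()[active]


def find_minima(
    gt: GroundTruth,
    box: list[tuple[float, float]],
    grid_n: int = 60,
    template: Configuration | None = None,
    merge_tol: float = 1e-3,
) -> list[tuple[np.ndarray, float]]:
    """Locate all local minima of a surface by grid search + local descent.

    ``box`` gives (lo, hi) per active coordinate.  Every grid-local minimum
    is refined by Nelder–Mead; duplicates within ``merge_tol`` are merged.
    Results are sorted by energy.
    """
    if grid_n < 50:
        raise ValueError("grid_n must be >= 50")
    if template is None:
        template = gt.make_configuration()
    template = template.copy()
    active = _active_coords(gt, template)
    ndim = len(box)
    if ndim != len(active):
        raise ValueError("box dimensionality must match active coordinates")
    axes = [np.linspace(lo, hi, grid_n) for lo, hi in box]
    grids = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    energies = np.array(
        [_energy_of(gt, template, active, p) for p in pts]
    ).reshape([grid_n] * ndim)

    def is_local_min(idx):
        e0 = energies[idx]
        for d in range(ndim):
            for step in (-1, 1):
                j = list(idx)
                j[d] += step
                if 0 <= j[d] < grid_n and energies[tuple(j)] < e0:
                    return False
        return True

    found: list[tuple[np.ndarray, float]] = []
    for idx in np.ndindex(*energies.shape):
        if not is_local_min(idx):
            continue
        x0 = np.array([axes[d][idx[d]] for d in range(ndim)])
        res = minimize(
            lambda x: _energy_grad_of(gt, template, active, x),
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"gtol": 1e-10, "maxiter": 5000},
        )
        x, e = res.x, res.fun
        lo = np.array([b[0] for b in box])
        hi = np.array([b[1] for b in box])
        if np.any(x < lo - 1e-6) or np.any(x > hi + 1e-6):
            continue
        for xf, _ in found:
            if np.linalg.norm(xf - x) < merge_tol:
                break
        else:
            found.append((x, float(e)))
    found.sort(key=lambda t: t[1])
    return found


def barrier_1d(
    gt: GroundTruth,
    cv,
    cv_range: tuple[float, float],
    grid_n: int = 400,
    template: Configuration | None = None,
) -> float:
    """Minimum-energy-path barrier between the two lowest basins of a surface.

    Scans the collective variable over ``cv_range`` on ``grid_n`` points,
    minimising the energy at each fixed CV value (constrained via a stiff
    quadratic penalty, followed by penalty-free refinement in the orthogonal
    subspace when the CV is an active coordinate itself).  Returns
    ``max(profile between the basins) − min(profile)`` in eV.
    """
    if template is None:
        template = gt.make_configuration()
    template = template.copy()
    active = _active_coords(gt, template)
    svals = np.linspace(cv_range[0], cv_range[1], grid_n)
    kappa = 1e4

    profile = np.empty(grid_n)
    x_prev = template.positions.ravel()[active].copy()
    for i, s_target in enumerate(svals):

        def penalised(x, s_target=s_target):
            e, g = _energy_grad_of(gt, template, active, x)
            s, gs = cv.value_gradient(template)
            pen = s - s_target
            return (
                e + kappa * pen * pen,
                g + 2.0 * kappa * pen * gs.ravel()[active],
            )

        res = minimize(penalised, x_prev, jac=True, method="L-BFGS-B",
                       options={"gtol": 1e-9, "maxiter": 4000})
        x_prev = res.x
        profile[i] = _energy_of(gt, template, active, res.x)

    # two lowest basins = local minima of the profile
    mins = [
        i
        for i in range(1, grid_n - 1)
        if profile[i] <= profile[i - 1] and profile[i] <= profile[i + 1]
    ]
    if len(mins) < 2:
        raise ValueError("fewer than 2 basins found along the CV range")
    mins.sort(key=lambda i: profile[i])
    i_a, i_b = sorted(mins[:2])
    seg = profile[i_a : i_b + 1]
    return float(seg.max() - min(profile[i_a], profile[i_b]))
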