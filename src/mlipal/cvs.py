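"""Collective variables (CVs) with analytic gradients, and restraint walls.

A CV maps a configuration to a scalar and exposes the per-atom gradient
∂s/∂x needed to convert a bias force dV/ds into atomic forces.  The CVs
implemented here are the ones reactive enhanced-sampling studies lean on:
a bond-length difference (e.g. r_breaking − r_forming) and a smooth
coordination number built from the rational switching function
[1 − (r/r0)⁶] / [1 − (r/r0)¹²].
"""

from __future__ import annotations

import numpy as np

from .configurations import Configuration

_R_MIN = 1e-9  # Å; below this two atoms are treated as coincident


class CollectiveVariable:
    """Contract: ``value(c)`` scalar, ``gradient(c)`` (N, 3) array ∂s/∂x."""

    name = "cv"
    atom_indices: tuple = ()

    def value(self, c: Configuration) -> float:
        return self.value_gradient(c)[0]

    def gradient(self, c: Configuration) -> np.ndarray:
        return self.value_gradient(c)[1]

    def value_gradient(self, c: Configuration) -> tuple[float, np.ndarray]:
        raise NotImplementedError


def _pair_distance(c: Configuration, i: int, j: int):
    v = c.positions[i] - c.positions[j]
    r = float(np.linalg.norm(v))
    if r < _R_MIN:
        raise FloatingPointError(f"atoms {i} and {j} are coincident (r={r:g} Å)")
    return r, v / r


class DistanceCV(CollectiveVariable):
    """s = |r_i − r_j| in Å."""

    def __init__(self, i: int, j: int, name: str = ""):
        self.i, self.j = int(i), int(j)
        self.atom_indices = (self.i, self.j)
        self.name = name or f"d({i},{j})"

    def value_gradient(self, c: Configuration):
        r, u = _pair_distance(c, self.i, self.j)
        g = np.zeros_like(c.positions)
        g[self.i] = u
        g[self.j] = -u
        return r, g


class DistanceDifferenceCV(CollectiveVariable):
    """s = r_ij − r_kl in Å — the classic substitution-reaction coordinate."""

    def __init__(self, pair_a: tuple[int, int], pair_b: tuple[int, int],
                 name: str = ""):
        self.pair_a = (int(pair_a[0]), int(pair_a[1]))
        self.pair_b = (int(pair_b[0]), int(pair_b[1]))
        self.atom_indices = (*self.pair_a, *self.pair_b)
        self.name = name or f"d{self.pair_a}-d{self.pair_b}"

    def value_gradient(self, c: Configuration):
        i, j = self.pair_a
        k, l = self.pair_b
        r1, u1 = _pair_distance(c, i, j)
        r2, u2 = _pair_distance(c, k, l)
        g = np.zeros_like(c.positions)
        g[i] += u1
        g[j] -= u1
        g[k] -= u2
        g[l] += u2
        return r1 - r2, g


class CoordinationNumberCV(CollectiveVariable):
    """Smooth bond-presence indicator s = [1 − (r/r0)⁶] / [1 − (r/r0)¹²].

    The removable singularity at r = r0 is eliminated algebraically:
    s = 1 / (1 + (r/r0)⁶), valid for all r ≥ 0, with s(r0) = 1/2,
    s → 1 as r → 0 and s → 0 as r → ∞.  Dimensionless.
    """

    def __init__(self, i: int, j: int, r0: float = 2.5, name: str = ""):
        self.i, self.j = int(i), int(j)
        self.r0 = float(r0)
        self.atom_indices = (self.i, self.j)
        self.name = name or f"cn({i},{j})"

    def switching(self, r: float) -> float:
        return 1.0 / (1.0 + (r / self.r0) ** 6)

    def value_gradient(self, c: Configuration):
        r, u = _pair_distance(c, self.i, self.j)
        q = (r / self.r0) ** 6
        s = 1.0 / (1.0 + q)
        dsdr = -6.0 * q / (r * (1.0 + q) ** 2)
        g = np.zeros_like(c.positions)
        g[self.i] = dsdr * u
        g[self.j] = -dsdr * u
        return s, g


class AxisPositionCV(CollectiveVariable):
    """One Cartesian coordinate of one atom — the CV of the toy surfaces."""

    def __init__(self, atom: int = 0, axis: int = 0, name: str = ""):
        self.atom, self.axis = int(atom), int(axis)
        self.atom_indices = (self.atom,)
        self.name = name or f"x[{atom},{'xyz'[axis]}]"

    def value_gradient(self, c: Configuration):
        g = np.zeros_like(c.positions)
        g[self.atom, self.axis] = 1.0
        return float(c.positions[self.atom, self.axis]), g


class WallRestraint:
    """One-sided harmonic wall keeping a scalar in [lower, upper].

    Energy κ·(violation)² outside the window, zero inside; the force is
    continuous at the boundary.  The restrained scalar is any CV (typically
    a raw bond length via :class:`DistanceCV`).  κ in eV per (CV unit)².
    """

    def __init__(self, cv: CollectiveVariable, lower: float, upper: float,
                 kappa: float = 100.0):
        if kappa <= 0:
            raise ValueError("kappa must be > 0")
        if not lower < upper:
            raise ValueError("need lower < upper")
        self.cv = cv
        self.lower, self.upper = float(lower), float(upper)
        self.kappa = float(kappa)
        self._zero = None  # cached inside-window zero force (never mutated)

    def energy_forces(self, c: Configuration) -> tuple[float, np.ndarray]:
        s, g = self.cv.value_gradient(c)
        if s < self.lower:
            v = s - self.lower
        elif s > self.upper:
            v = s - self.upper
        else:
            if self._zero is None or self._zero.shape != c.positions.shape:
                self._zero = np.zeros_like(c.positions)
            return 0.0, self._zero
        e = self.kappa * v * v
        return e, -2.0 * self.kappa * v * g
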