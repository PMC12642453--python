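"""Kernel-ridge surrogate fulfilling the MLIP contract, plus its descriptor.

The regressor is intentionally architecture-agnostic: anything exposing
``train(dataset)`` / ``predict(configuration) -> (energy, forces)`` can be
dropped into the active-learning loop in its place.  The built-in model is
kernel ridge regression with an RBF kernel on a permutation- and
rotation-invariant pairwise descriptor:

* for ordinary molecules, each unordered element-pair channel collects all
  ``exp(-r / r_scale)`` values of that pair type, sorted descending and
  zero-padded to a fixed length;
* for the designated-coordinate toy systems (any configuration carrying a
  ``frozen_axes`` mask) the descriptor is simply the vector of mobile
  coordinates, which is the natural exact featurisation of those surfaces.

The same descriptor backs the similarity selector (cosine similarity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve
from scipy.spatial.distance import pdist

from .configurations import Configuration, Dataset

_TIE_TOL = 1e-10  # sorted-channel tie threshold triggering FD force fallback
_FD_STEP = 1e-4  # Å, central-difference step of the force fallback


@dataclass
class DescriptorSpec:
    """Pairwise-channel descriptor parameters.

    ``r_scale`` is the exponential decay length (Å); ``pad`` is the number
    of slots reserved per element-pair channel.
    """

    r_scale: float = 1.0
    pad: int = 16


def _is_toy(c: Configuration) -> bool:
    return c.frozen_axes is not None and bool(c.frozen_axes.any())


def _channels(elements: list[str]) -> list[tuple[str, str]]:
    kinds = sorted(set(elements))
    return [
        (a, b) for ai, a in enumerate(kinds) for b in kinds[ai:]
    ]


def featurize(spec: DescriptorSpec, c: Configuration,
              jacobian: bool = False):
    """Map a configuration to its fixed-length descriptor vector.

    With ``jacobian=True`` additionally returns the (n_features, N*3)
    matrix ∂d/∂x, or None when sorted-channel ties make the analytic
    Jacobian ambiguous.
    """
    if _is_toy(c):
        active = np.flatnonzero(~c.frozen_axes.ravel())
        d = c.positions.ravel()[active].copy()
        if not jacobian:
            return d
        J = np.zeros((d.size, c.positions.size))
        J[np.arange(d.size), active] = 1.0
        return d, J

    if c.n_atoms < 2:
        raise ValueError("pairwise descriptor needs at least 2 atoms")
    chans = _channels(c.elements)
    chan_index = {pair: k for k, pair in enumerate(chans)}
    per_chan_vals: list[list[tuple[float, int, int]]] = [[] for _ in chans]
    for i in range(c.n_atoms):
        for j in range(i + 1, c.n_atoms):
            pair = tuple(sorted((c.elements[i], c.elements[j])))
            r = float(np.linalg.norm(c.positions[i] - c.positions[j]))
            per_chan_vals[chan_index[pair]].append(
                (np.exp(-r / spec.r_scale), i, j)
            )
    d = np.zeros(len(chans) * spec.pad)
    entries = []  # (feature slot, value, i, j)
    for k, vals in enumerate(per_chan_vals):
        if len(vals) > spec.pad:
            raise ValueError(
                f"channel {chans[k]} has {len(vals)} pair distances; "
                f"increase DescriptorSpec.pad (currently {spec.pad})"
            )
        vals.sort(key=lambda t: t[0], reverse=True)
        for m, (v, i, j) in enumerate(vals):
            slot = k * spec.pad + m
            d[slot] = v
            entries.append((slot, v, i, j))
    if not jacobian:
        return d

    # ties inside one channel make the sort permutation non-differentiable
    for k, vals in enumerate(per_chan_vals):
        for m in range(1, len(vals)):
            if abs(vals[m - 1][0] - vals[m][0]) < _TIE_TOL:
                return d, None
    J = np.zeros((d.size, c.positions.size))
    for slot, v, i, j in entries:
        u = c.positions[i] - c.positions[j]
        r = np.linalg.norm(u)
        dv_dr = -v / spec.r_scale
        grad_i = dv_dr * u / r
        J[slot, 3 * i : 3 * i + 3] = grad_i
        J[slot, 3 * j : 3 * j + 3] = -grad_i
    return d, J


def similarity(spec: DescriptorSpec, a: Configuration, b: Configuration) -> float:
    """Cosine similarity of descriptors, clipped to [0, 1]; 1 for identity."""
    if sorted(a.elements) != sorted(b.elements):
        raise ValueError("similarity requires identical element composition")
    da = featurize(spec, a)
    db = featurize(spec, b)
    na, nb = np.linalg.norm(da), np.linalg.norm(db)
    if na == 0.0 or nb == 0.0:
        raise ValueError("zero-norm descriptor; similarity undefined")
    return float(np.clip(da @ db / (na * nb), 0.0, 1.0))


@dataclass
class TrainConfig:
    energy_weight: float = 1.0
    force_weight: float = 0.0  # stored labels only; energy-only fit
    seed: int = 0

    def __post_init__(self):
        if self.energy_weight < 0 or self.force_weight < 0:
            raise ValueError("weights must be >= 0")
        if self.energy_weight == 0 and self.force_weight == 0:
            raise ValueError("at least one weight must be positive")


class SurrogateModel:
    """RBF kernel-ridge regressor over the pairwise descriptor.

    Energies are centred on their mean before fitting; the kernel
    length-scale defaults to the median pairwise descriptor distance of the
    training set (the median heuristic).  Forces come from the analytic
    chain rule through the descriptor, falling back to central finite
    differences when sorted-channel ties make the Jacobian ambiguous.
    """

    FORMAT_TAG = "mlipal-krr-1"

    def __init__(self, descriptor: DescriptorSpec | None = None,
                 length_scale: float | None = None, ridge: float = 1e-8,
                 energy_clip: float | None = None):
        self.descriptor = descriptor or DescriptorSpec()
        self.length_scale = length_scale
        self.ridge = float(ridge)
        # clamp training energies at (dataset min + energy_clip) eV; keeps
        # rare very-high-energy configurations as repulsive anchors without
        # letting them dominate the kernel fit
        self.energy_clip = energy_clip
        self.centers: np.ndarray | None = None
        self.weights: np.ndarray | None = None
        self.baseline: float = 0.0

    @property
    def trained(self) -> bool:
        return self.weights is not None

    def train(self, ds: Dataset, cfg: TrainConfig | None = None) -> "SurrogateModel":
        """Fit on every labelled item of ``ds`` (in insertion order)."""
        labelled = [c for c in ds if c.energy is not None]
        if not labelled:
            raise ValueError("no labelled configurations to train on")
        X = np.array([featurize(self.descriptor, c) for c in labelled])
        y = np.array([c.energy for c in labelled])
        if self.energy_clip is not None:
            y = np.minimum(y, y.min() + self.energy_clip)
        if self.length_scale is None:
            if len(labelled) > 1:
                dists = pdist(X)
                med = float(np.median(dists[dists > 0])) if (dists > 0).any() else 1.0
            else:
                med = 1.0
            self._ell = med
        else:
            self._ell = float(self.length_scale)
        self.baseline = float(y.mean())
        K = self._kernel(X, X)
        K[np.diag_indices_from(K)] += self.ridge
        try:
            self.weights = solve(K, y - self.baseline, assume_a="pos")
        except np.linalg.LinAlgError:
            self.weights = np.linalg.lstsq(K, y - self.baseline, rcond=None)[0]
        self.centers = X
        return self

    def _kernel(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        a2 = (A * A).sum(axis=1)[:, None]
        b2 = (B * B).sum(axis=1)[None, :]
        sq = np.maximum(a2 + b2 - 2.0 * A @ B.T, 0.0)
        return np.exp(-sq / (2.0 * self._ell**2))

    def predict_energy(self, c: Configuration) -> float:
        if not self.trained:
            raise RuntimeError("model is not trained")
        d = featurize(self.descriptor, c)
        k = self._kernel(d[None, :], self.centers)[0]
        return float(self.baseline + k @ self.weights)

    def predict(self, c: Configuration) -> tuple[float, np.ndarray]:
        """Energy (eV) and forces (eV Å⁻¹) at ``c``."""
        if not self.trained:
            raise RuntimeError("model is not trained")
        out = featurize(self.descriptor, c, jacobian=True)
        d, J = out
        k = self._kernel(d[None, :], self.centers)[0]
        energy = float(self.baseline + k @ self.weights)
        if J is None:
            forces = self._fd_forces(c)
        else:
            # dE/dd = sum_i w_i k_i (x_i - d) / ell^2
            gfeat = ((self.centers - d[None, :]) / self._ell**2).T @ (
                k * self.weights
            )
            forces = (-(J.T @ gfeat)).reshape(-1, 3)
        if c.frozen_axes is not None:
            forces = forces.copy()
            forces[c.frozen_axes] = 0.0
        return energy, forces

    # the composite-potential protocol used by the dynamics module
    energy_forces = predict

    def _fd_forces(self, c: Configuration) -> np.ndarray:
        work = c.copy()
        f = np.zeros_like(c.positions)
        for i in range(c.n_atoms):
            for ax in range(3):
                if c.frozen_axes is not None and c.frozen_axes[i, ax]:
                    continue
                for sgn in (1.0, -1.0):
                    work.positions[:] = c.positions
                    work.positions[i, ax] += sgn * _FD_STEP
                    f[i, ax] -= sgn * self.predict_energy(work)
                f[i, ax] /= 2.0 * _FD_STEP
        return f

    # ---------------- serialisation ----------------

    def save(self, path) -> None:
        if not self.trained:
            raise RuntimeError("cannot save an untrained model")
        blob = {
            "format": self.FORMAT_TAG,
            "descriptor": {"r_scale": self.descriptor.r_scale,
                           "pad": self.descriptor.pad},
            "length_scale": self._ell,
            "ridge": self.ridge,
            "baseline": self.baseline,
            "centers": self.centers.tolist(),
            "weights": self.weights.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(blob, fh)

    @classmethod
    def load(cls, path) -> "SurrogateModel":
        with open(path) as fh:
            blob = json.load(fh)
        if blob.get("format") != cls.FORMAT_TAG:
            raise ValueError(f"unrecognised model format {blob.get('format')!r}")
        m = cls(DescriptorSpec(**blob["descriptor"]), ridge=blob["ridge"])
        m._ell = blob["length_scale"]
        m.baseline = blob["baseline"]
        m.centers = np.array(blob["centers"])
        m.weights = np.array(blob["weights"])
        return m
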