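"""Molecular configurations, datasets and extended-XYZ I/O.

A :class:`Configuration` is the universal currency of the package: a set of
atomic positions with element symbols and masses, optionally labelled with a
ground-truth energy (eV) and forces (eV Å⁻¹), plus a provenance ``tag``.
Toy low-dimensional systems are embedded in 3D via ``frozen_axes``, a
per-atom boolean mask marking coordinates the dynamics must never move.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import ATOMIC_MASSES


class ExtXYZParseError(ValueError):
    """Raised for malformed extended-XYZ input; carries the line number."""


@dataclass
class Configuration:
    """A single molecular structure with optional energy/force labels.

    Parameters
    ----------
    positions
        (N, 3) Cartesian coordinates in Å.
    elements
        Length-N chemical symbols.  ``"X"`` is accepted as a dummy species
        (mass 1 amu) for toy systems.
    masses
        Per-atom masses in amu; looked up from the element table when
        omitted.
    energy, forces
        Optional labels in eV and eV Å⁻¹.
    tag
        Free-form provenance string, e.g. ``"al-iter-7/traj-2"``.
    frozen_axes
        Optional (N, 3) boolean mask; True entries are immobile coordinates.
    """

    positions: np.ndarray
    elements: list[str]
    masses: np.ndarray | None = None
    energy: float | None = None
    forces: np.ndarray | None = None
    tag: str = ""
    frozen_axes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.elements = list(self.elements)
        n = len(self.elements)
        if n < 1 or self.positions.shape != (n, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{n} element symbols"
            )
        if self.masses is None:
            try:
                self.masses = np.array(
                    [ATOMIC_MASSES[e] for e in self.elements], dtype=float
                )
            except KeyError as exc:
                raise ValueError(f"unknown element symbol {exc}") from None
        else:
            self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != (n,) or np.any(self.masses <= 0):
            raise ValueError("masses must be positive, one per atom")
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float).reshape(-1, 3)
            if self.forces.shape != self.positions.shape:
                raise ValueError("forces must have the same shape as positions")
        if self.energy is not None:
            self.energy = float(self.energy)
        if self.frozen_axes is not None:
            self.frozen_axes = np.asarray(self.frozen_axes, dtype=bool).reshape(-1, 3)
            if self.frozen_axes.shape != self.positions.shape:
                raise ValueError("frozen_axes must have the same shape as positions")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def labelled(self) -> bool:
        """True when both an energy and forces label are present."""
        return self.energy is not None and self.forces is not None

    def copy(self, **overrides) -> "Configuration":
        """Deep copy, with optional field overrides (``energy=None`` clears)."""
        kwargs = dict(
            positions=self.positions.copy(),
            elements=list(self.elements),
            masses=self.masses.copy(),
            energy=self.energy,
            forces=None if self.forces is None else self.forces.copy(),
            tag=self.tag,
            frozen_axes=None if self.frozen_axes is None else self.frozen_axes.copy(),
        )
        kwargs.update(overrides)
        return Configuration(**kwargs)


class Dataset:
    """Insertion-ordered collection of configurations.

    Order is preserved so that the active-learning selector history can be
    reconstructed from the dataset alone.
    """

    def __init__(self, items: list[Configuration] | None = None):
        self.items: list[Configuration] = list(items) if items else []

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i):
        return self.items[i]

    @property
    def labelled_count(self) -> int:
        return sum(1 for c in self.items if c.labelled)

    def append(self, c: Configuration) -> None:
        self.items.append(c)


def dataset_append_unique(ds: Dataset, c: Configuration, tol: float) -> bool:
    """Append ``c`` unless a same-size item lies within ``tol`` of it.

    Two configurations are considered duplicates when the maximum per-atom
    displacement between them is below ``tol`` (Å).  Items with a different
    atom count never block an append.  Returns True when appended.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    if tol > 0:
        for item in ds.items:
            if item.n_atoms != c.n_atoms:
                continue
            d = np.linalg.norm(item.positions - c.positions, axis=1)
            if d.max() < tol:
                return False
    ds.append(c)
    return True


def random_displace(
    ref: Configuration,
    count: int,
    magnitude: float = 0.1,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[Configuration]:
    """Generate ``count`` randomly displaced copies of ``ref``.

    Each mobile coordinate is shifted by an independent uniform draw from
    ``[-magnitude, +magnitude]`` Å; frozen axes are untouched and labels are
    cleared.  Reproducible for a fixed ``seed``.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    if magnitude < 0:
        raise ValueError("magnitude must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = []
    for i in range(count):
        delta = rng.uniform(-magnitude, magnitude, size=ref.positions.shape)
        if ref.frozen_axes is not None:
            delta[ref.frozen_axes] = 0.0
        out.append(
            ref.copy(
                positions=ref.positions + delta,
                energy=None,
                forces=None,
                tag=f"{ref.tag or 'init'}/displaced-{i}",
            )
        )
    return out


# --------------------------------------------------------------------------
# Extended-XYZ I/O (comment-line key=value dialect).
#
# The only keys written are `energy` and
# `Properties=species:S:1:pos:R:3[:forces:R:3]`, which is the subset every
# extended-XYZ reader understands.  Units are eV and eV Å⁻¹.
# --------------------------------------------------------------------------

def write_extxyz(configs: list[Configuration], path) -> None:
    """Write configurations as a multi-frame extended-XYZ file."""
    with open(path, "w") as fh:
        for c in configs:
            props = "species:S:1:pos:R:3"
            if c.forces is not None:
                props += ":forces:R:3"
            comment = f"Properties={props}"
            if c.energy is not None:
                comment += f" energy={c.energy!r}"
            if c.tag:
                comment += f' tag="{c.tag}"'
            fh.write(f"{c.n_atoms}\n{comment}\n")
            for i in range(c.n_atoms):
                row = f"{c.elements[i]:2s} " + " ".join(
                    f"{float(x)!r}" for x in c.positions[i]
                )
                if c.forces is not None:
                    row += " " + " ".join(f"{float(x)!r}" for x in c.forces[i])
                fh.write(row + "\n")


def _parse_comment(line: str) -> dict:
    """Parse the key=value comment line (values may be double-quoted)."""
    out: dict[str, str] = {}
    i, n = 0, len(line)
    while i < n:
        if line[i].isspace():
            i += 1
            continue
        eq = line.find("=", i)
        if eq < 0:
            break
        key = line[i:eq].strip()
        j = eq + 1
        if j < n and line[j] == '"':
            end = line.find('"', j + 1)
            val = line[j + 1 : end]
            i = end + 1
        else:
            end = j
            while end < n and not line[end].isspace():
                end += 1
            val = line[j:end]
            i = end
        out[key] = val
    return out


def read_extxyz(path) -> list[Configuration]:
    """Read a (multi-frame) extended-XYZ file into configurations.

    The comment-line ``energy`` key and per-atom ``forces`` columns, when
    present, populate the labels (units eV and eV Å⁻¹).
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    configs: list[Configuration] = []
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            nat = int(lines[ln].strip())
        except ValueError:
            raise ExtXYZParseError(
                f"line {ln + 1}: expected an atom count, got {lines[ln]!r}"
            ) from None
        if ln + 2 + nat > len(lines):
            raise ExtXYZParseError(f"line {ln + 1}: truncated frame ({nat} atoms)")
        keys = _parse_comment(lines[ln + 1])
        props = keys.get("Properties", "species:S:1:pos:R:3")
        fields = props.split(":")
        has_forces = "forces" in fields[::3]
        elements, pos, forces = [], [], []
        for k in range(nat):
            parts = lines[ln + 2 + k].split()
            want = 7 if has_forces else 4
            if len(parts) < want:
                raise ExtXYZParseError(
                    f"line {ln + 3 + k}: expected {want} columns, got {len(parts)}"
                )
            sym = parts[0]
            if sym not in ATOMIC_MASSES:
                raise ValueError(f"line {ln + 3 + k}: unknown element symbol {sym!r}")
            elements.append(sym)
            pos.append([float(x) for x in parts[1:4]])
            if has_forces:
                forces.append([float(x) for x in parts[4:7]])
        configs.append(
            Configuration(
                positions=np.array(pos),
                elements=elements,
                energy=float(keys["energy"]) if "energy" in keys else None,
                forces=np.array(forces) if has_forces else None,
                tag=keys.get("tag", ""),
            )
        )
        ln += 2 + nat
    return configs
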