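"""YAML run-configuration schema with strict validation.

A run configuration has the sections below; every key has a default that
mirrors the workflow's canonical values, unknown keys are rejected, and all
schema violations in a file are reported at once.

Units: distances Å, energies eV, times fs, temperatures K.  The Langevin
friction is given per natural time unit (``friction_per_tau``), matching
the convention of the dynamics module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .active_learning import ALConfig
from .cvs import (AxisPositionCV, CoordinationNumberCV, DistanceCV,
                  DistanceDifferenceCV, WallRestraint)
from .dynamics import MDParams
from .surfaces import DoubleWell1D, MuellerBrown2D, TriatomicExchange
from .units import TAU0

_SURFACES = {
    "double-well": DoubleWell1D,
    "mueller-brown": MuellerBrown2D,
    "triatomic": TriatomicExchange,
}

# section -> {key: default}; None means "no default, optional"
_SCHEMA = {
    "ground_truth": {"surface": "double-well", "params": {}},
    "system": {"structure": None, "fixture": None},
    "cvs": [],            # list of CV mappings, validated separately
    "walls": [],          # list of wall mappings
    "mlip": {"r_scale": 1.0, "pad": 16, "ridge": 1e-8, "length_scale": None},
    "md": {"timestep": 0.5, "temperature": 300.0, "friction_per_tau": 0.02,
           "n_steps": 1000, "ensemble": "langevin", "stride": 1},
    "metad": {"h0": 0.013, "gamma": 50.0, "sigma": 0.1, "tau_deposit": 25.0},
    "al": {"mode": "wtmetad-ib", "init_count": 8, "init_magnitude": 0.1,
           "temperature": None, "n_parallel": 4, "max_md_time": 1000.0,
           "max_iterations": 50, "selector": "energy",
           "energy_threshold": 0.1, "similarity_threshold": 0.9995,
           "reset_n_on_selection": True},
    "fes": {"bins": 200, "tol": 1e-7, "bandwidth": 0.02, "grid_min": -2.0,
            "grid_max": 2.0, "grid_n": 401, "reps": 5, "time": 10000.0,
            "k": 15.0, "equil": 0.0, "time_per_window": 1000.0,
            "centers": None},
    "classify": {"conditions": []},
    "seeds": {"master": 0},
}

_CV_KEYS = {"type", "atoms", "pairs", "r0", "axis", "atom", "name"}
_WALL_KEYS = {"atoms", "lower", "upper", "kappa"}


class ConfigError(ValueError):
    """Raised with every schema problem found, one per line."""


@dataclass
class RunConfig:
    """Resolved configuration: raw section dicts plus object factories."""

    sections: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.sections[key]

    def make_ground_truth(self):
        gt_cfg = self.sections["ground_truth"]
        cls = _SURFACES[gt_cfg["surface"]]
        return cls(**gt_cfg["params"])

    def make_cvs(self):
        out = []
        for spec in self.sections["cvs"]:
            kind = spec["type"]
            name = spec.get("name", "")
            if kind == "distance":
                i, j = spec["atoms"]
                out.append(DistanceCV(i, j, name=name))
            elif kind == "distance_difference":
                (i, j), (k, l) = spec["pairs"]
                out.append(DistanceDifferenceCV((i, j), (k, l), name=name))
            elif kind == "coordination":
                i, j = spec["atoms"]
                out.append(CoordinationNumberCV(i, j, r0=spec.get("r0", 2.5),
                                                name=name))
            elif kind == "axis":
                out.append(AxisPositionCV(spec.get("atom", 0),
                                          spec.get("axis", 0), name=name))
            else:
                raise ConfigError(f"unknown CV type {kind!r}")
        return out

    def make_walls(self):
        walls = []
        for spec in self.sections["walls"]:
            i, j = spec["atoms"]
            walls.append(WallRestraint(DistanceCV(i, j),
                                       lower=spec["lower"],
                                       upper=spec["upper"],
                                       kappa=spec.get("kappa", 100.0)))
        return walls

    def make_md_params(self, **overrides) -> MDParams:
        md = dict(self.sections["md"])
        md.update(overrides)
        return MDParams(timestep=md["timestep"], temperature=md["temperature"],
                        friction=md["friction_per_tau"] / TAU0,
                        n_steps=int(md["n_steps"]), ensemble=md["ensemble"],
                        seed=self.sections["seeds"]["master"])

    def make_al_config(self) -> ALConfig:
        al = self.sections["al"]
        metad = self.sections["metad"]
        mlip = self.sections["mlip"]
        md = self.sections["md"]
        return ALConfig(
            mode=al["mode"], init_count=al["init_count"],
            init_magnitude=al["init_magnitude"],
            temperature=al["temperature"], n_parallel=al["n_parallel"],
            max_md_time=al["max_md_time"],
            max_iterations=al["max_iterations"], selector=al["selector"],
            energy_threshold=al["energy_threshold"],
            similarity_threshold=al["similarity_threshold"],
            h0=metad["h0"], gamma=metad["gamma"], sigma=metad["sigma"],
            tau_deposit=metad["tau_deposit"], timestep=md["timestep"],
            friction=md["friction_per_tau"] / TAU0,
            md_stride=md["stride"],
            descriptor_r_scale=mlip["r_scale"], descriptor_pad=mlip["pad"],
            ridge=mlip["ridge"],
            reset_n_on_selection=al["reset_n_on_selection"],
            seed=self.sections["seeds"]["master"],
        )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Defaults are materialised for every missing key; unknown sections or
    keys are collected and reported together.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    problems = []
    resolved = {}
    for section, defaults in _SCHEMA.items():
        got = raw.get(section, [] if isinstance(defaults, list) else {})
        if isinstance(defaults, list):
            if not isinstance(got, list):
                problems.append(f"section {section!r} must be a list")
                got = []
            allowed = _CV_KEYS if section == "cvs" else _WALL_KEYS
            for idx, item in enumerate(got):
                for key in item:
                    if key not in allowed:
                        problems.append(
                            f"{section}[{idx}]: unknown key {key!r} "
                            f"(allowed: {sorted(allowed)})"
                        )
            resolved[section] = got
        else:
            if not isinstance(got, dict):
                problems.append(f"section {section!r} must be a mapping")
                got = {}
            merged = dict(defaults)
            for key, val in got.items():
                if key not in defaults:
                    problems.append(
                        f"{section}.{key}: unknown key "
                        f"(allowed: {sorted(defaults)})"
                    )
                else:
                    merged[key] = val
            resolved[section] = merged
    for section in raw:
        if section not in _SCHEMA:
            problems.append(
                f"unknown section {section!r} (allowed: {sorted(_SCHEMA)})"
            )
    if problems:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(problems))
    return RunConfig(sections=resolved)
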