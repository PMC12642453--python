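"""Free-energy-surface container shared by the estimators."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import KCAL_PER_MOL_IN_EV


@dataclass
class FESEstimate:
    """Free energy on a CV grid, min-shifted to zero.

    ``sigma`` is the per-grid-point standard deviation across independent
    repeats (zeros for a single estimate); the 95% band is
    1.96·sigma/sqrt(n_reps).
    """

    grid: np.ndarray
    F: np.ndarray                  # eV, min 0
    sigma: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        finite = np.isfinite(self.F)
        if finite.any():
            self.F = self.F - self.F[finite].min()
        if self.sigma is None:
            self.sigma = np.zeros_like(self.F)
        else:
            self.sigma = np.asarray(self.sigma, dtype=float)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("cv\tF_eV\tF_kcal_per_mol\tsigma_eV\n")
            for g, f, s in zip(self.grid, self.F, self.sigma):
                fh.write(f"{float(g)!r}\t{float(f)!r}\t{float(f / KCAL_PER_MOL_IN_EV)!r}\t{float(s)!r}\n")

    @classmethod
    def read_tsv(cls, path) -> "FESEstimate":
        data = np.loadtxt(path, skiprows=1)
        return cls(grid=data[:, 0], F=data[:, 1], sigma=data[:, 3])
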