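"""Project-wide unit system and physical constants.

Everything in the package works in Å, eV, fs, K and amu.  The natural time
unit of this system, ``TAU0 = sqrt(amu * Å**2 / eV)`` ≈ 10.18 fs, links the
mechanical units: an acceleration of 1 eV Å⁻¹ amu⁻¹ equals ``1 / TAU0**2``
Å fs⁻².  Friction coefficients quoted "per natural time unit" are converted
to fs⁻¹ by dividing by ``TAU0``.
"""

import math

#: Boltzmann constant, eV K⁻¹.
KB = 8.617333262e-5

#: Atomic mass unit, kg (CODATA 2018).
_AMU_KG = 1.66053906660e-27
#: Elementary charge, C — also J per eV (exact, SI 2019).
_E_C = 1.602176634e-19

#: Natural time unit sqrt(amu Å² / eV) expressed in fs.
TAU0 = math.sqrt(_AMU_KG * 1e-20 / _E_C) * 1e15  # ≈ 10.180506 fs

#: Conversion: (eV Å⁻¹ / amu) -> Å fs⁻².
FORCE_TO_ACC = 1.0 / TAU0**2

#: Conversion: amu (Å/fs)² -> eV, used for kinetic energies.
MASS_VEL2_TO_EV = TAU0**2

#: Avogadro constant, mol⁻¹ (exact).
_N_A = 6.02214076e23

#: 1 kcal mol⁻¹ in eV (exact definition: 1 kcal = 4184 J).
KCAL_PER_MOL_IN_EV = 4184.0 / (_N_A * _E_C)

#: Standard atomic masses (amu) for the elements used by the fixtures.
ATOMIC_MASSES = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948, "K": 39.098, "Ca": 40.078,
    "Br": 79.904, "I": 126.90, "X": 1.0,
}
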