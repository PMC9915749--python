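"""Physical constants for the "real"-style unit system.

Base units: length in angstrom (A), time in femtoseconds (fs), energy in
kcal/mol, mass in atomic mass units (amu), temperature in kelvin.  Forces are
therefore kcal mol^-1 A^-1 and stresses kcal mol^-1 A^-3.
"""

from __future__ import annotations

import math

#: Boltzmann constant, kcal mol^-1 K^-1.
KB = 1.987204259e-3

#: Avogadro constant, mol^-1.
NA = 6.02214076e23

#: Thermochemical calorie, J.
CAL = 4.184

#: Conversion of mass*velocity^2 (amu A^2 fs^-2) to energy (kcal/mol).
#: 1 amu A^2/fs^2 = 1e-3 kg/mol * 1e-20 m^2 / 1e-30 s^2 = 1e7 J/mol.
MVV2E = 1.0e7 / (CAL * 1000.0)  # = 2390.0573...

#: Conversion of force/mass (kcal mol^-1 A^-1 / amu) to acceleration (A fs^-2).
FTM2V = 1.0 / MVV2E

#: 1 kcal mol^-1 A^-3 expressed in MPa.
#: 4184 J/mol / NA / 1e-30 m^3 = 6.9477e9 Pa.
KCAL_PER_MOL_A3_TO_MPA = CAL * 1000.0 / NA / 1.0e-30 / 1.0e6

#: Factor between the LJ zero crossing sigma and the potential minimum.
LJ_MIN_FACTOR = 2.0 ** (1.0 / 6.0)


def thermal_velocity_std(mass: float, temperature: float) -> float:
    """Standard deviation of one Cartesian velocity component (A/fs) at T."""
    return math.sqrt(KB * temperature / (mass * MVV2E))
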