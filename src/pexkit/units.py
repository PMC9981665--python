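"""Internal unit system.

pexkit works in CHARMM-style "academic" units throughout:

========  =====================
length    angstrom (A)
energy    kcal/mol
charge    elementary charge (e)
time      ps
mass      amu (g/mol)
temp      K
========  =====================

In these units the Coulomb energy between two unit charges 1 A apart is
``COULOMB_CONSTANT`` kcal/mol, and thermal energy at 300 K is
``BOLTZMANN_KCAL * 300`` ~ 0.596 kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import constants as _c

#: Coulomb prefactor 1/(4 pi eps0) in kcal * A / (mol * e^2).
COULOMB_CONSTANT = 332.0716

#: Boltzmann constant in kcal / (mol * K).
BOLTZMANN_KCAL = 0.0019872041

#: 1 amu * A^2 / ps^2 expressed in kcal/mol (converts kinetic-style terms).
AMU_A2_PS2_IN_KCAL_MOL = _c.atomic_mass * 1e-20 / 1e-24 * _c.Avogadro / (_c.calorie * 1000.0)

#: sigma(0) in e^2 / (A * kcal/mol * ps) -> mS/cm.
CONDUCTIVITY_TO_MS_CM = (
    _c.elementary_charge**2
    / (1e-10 * (_c.calorie * 1000.0 / _c.Avogadro) * 1e-12)  # -> S/m
    * 10.0  # S/m -> mS/cm
)

KCAL_PER_KJ = 1.0 / 4.184

#: A^2/ps -> m^2/s.
A2_PS_TO_M2_S = 1e-20 / 1e-12


@dataclass(frozen=True)
class UnitSystem:
    """Fixed physical constants for one run.

    Frozen at construction so every module in a pipeline agrees on the
    Coulomb prefactor and k_B.
    """

    coulomb_constant: float = COULOMB_CONSTANT
    boltzmann_constant: float = BOLTZMANN_KCAL

    def __post_init__(self) -> None:
        if self.coulomb_constant <= 0:
            raise ValueError("coulomb_constant must be positive")
        if self.boltzmann_constant <= 0:
            raise ValueError("boltzmann_constant must be positive")

    def kT(self, temperature: float) -> float:
        """Thermal energy k_B*T in kcal/mol."""
        return self.boltzmann_constant * temperature


DEFAULT_UNITS = UnitSystem()
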