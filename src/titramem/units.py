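"""Units and thermodynamic context.

Internal units are nm and kJ/mol throughout the package; user-facing
profiles are reported in Angstrom (and PMFs in kcal/mol).  Conversion
happens only at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Boltzmann constant in kJ mol^-1 K^-1.
KB = 0.0083145

LN10 = math.log(10.0)

#: kJ per kcal (thermochemical calorie).
KJ_PER_KCAL = 4.184

ANGSTROM_PER_NM = 10.0


@dataclass(frozen=True)
class ThermoContext:
    """Inverse temperature and the pH-to-energy conversion factor.

    Attributes
    ----------
    temperature : float
        Absolute temperature in K.
    """

    temperature: float = 300.0

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise ValueError(f"temperature must be > 0, got {self.temperature}")

    @property
    def kT(self) -> float:
        """Thermal energy k_B*T in kJ/mol."""
        return KB * self.temperature

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/(k_B*T) in mol/kJ."""
        return 1.0 / self.kT

    @property
    def ln10_kT(self) -> float:
        """ln(10)*k_B*T in kJ/mol: the free-energy cost of one pH unit."""
        return LN10 * self.kT
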