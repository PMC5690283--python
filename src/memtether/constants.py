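"""Physical constants and unit conversions.

Unit convention throughout the package: lengths in nm, forces in pN,
times in s, energies in units of kBT, concentrations in mol/L.  All
conversions between number density (nm^-3) and molarity go through a
single :class:`Constants` instance so that no module hard-codes a
conversion factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Thermal energy kBT in pN nm at room temperature (~23 C, 296 K).
KBT_ROOM = 4.09

#: Avogadro constant, per mole (SI exact value).
AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class Constants:
    """Experiment-level physical constants.

    Parameters
    ----------
    thermal_energy:
        kBT in pN nm.  Default corresponds to room temperature (~23 C).
    avogadro:
        Avogadro constant, mol^-1.
    """

    thermal_energy: float = KBT_ROOM
    avogadro: float = AVOGADRO

    def __post_init__(self) -> None:
        if not self.thermal_energy > 0:
            raise ValueError("thermal_energy must be positive")
        if not self.avogadro > 0:
            raise ValueError("avogadro must be positive")

    @property
    def molar_conversion(self) -> float:
        """Factor converting a number density in nm^-3 to mol/L.

        1 nm^-3 = 1e24 / N_A mol/L (1 L = 1e24 nm^3), exactly.
        """
        return 1e24 / self.avogadro

    def density_to_molar(self, density_nm3: float) -> float:
        """Convert a number density in nm^-3 to a concentration in mol/L."""
        return density_nm3 * self.molar_conversion

    def molar_to_density(self, molar: float) -> float:
        """Convert a concentration in mol/L to a number density in nm^-3."""
        return molar / self.molar_conversion


#: Module-level default constants used when an API accepts ``constants=None``.
DEFAULT_CONSTANTS = Constants()
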