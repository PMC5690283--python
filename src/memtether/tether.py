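"""Tether-correction theory: from tethered to bimolecular binding.

A protein held near the membrane by a polypeptide tether binds with an
apparent (tethered) energy Eb and rate k_b that are inflated relative to
the bimolecular quantities by the local effective concentration c of the
tethered ligand.  With c_bar the average effective concentration on the
membrane (mol/L):

* k_on = k_b / c_bar                  (bimolecular on-rate, M^-1 s^-1)
* K_on = K_b / c_bar                  (binding constant)
* E_on = E_b + dEc,  dEc = -ln(c_bar / 1 M)   (energies in kBT)

The unbinding rate k_ub is unaffected by the tether.  For a tandem pair of
domains joined by a short linker, binding of one domain tethers the other
at the membrane, adding a coupling energy ln(c / 1 M) to the pair energy:
E_AB = E_A + E_B + ln(c).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

from .constants import DEFAULT_CONSTANTS, Constants
from .polymer import (
    CONTOUR_PER_AA,
    PEPTIDE_PERSISTENCE,
    GaussianTether,
    average_effective_concentration,
)

__all__ = [
    "TetheredBindingMeasurement",
    "CorrectedBinding",
    "TandemDecomposition",
    "correct_measurement",
    "correction_energy",
    "coupling_concentration",
    "decompose_tandem",
]

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class TetheredBindingMeasurement:
    """Zero-force binding parameters measured with the membrane tether in place.

    Energies in kBT; rate columns as log10 of s^-1 (mirroring how such
    tables are reported).  ``frame`` tags the record so a correction cannot
    be applied twice.
    """

    binding_energy: Optional[float] = None  # Eb, kBT
    log10_binding_rate: Optional[float] = None  # log10(k_b / s^-1)
    log10_unbinding_rate: Optional[float] = None  # log10(k_ub / s^-1)
    equilibrium_force: Optional[float] = None  # pN
    condition: Mapping[str, object] = field(default_factory=dict)
    uncertainties: Mapping[str, float] = field(default_factory=dict)
    frame: str = "tethered"

    def check_consistency(self, n_sd: float = 3.0) -> bool:
        """Check Eb/ln(10) ~ log10(k_b) - log10(k_ub) within uncertainty.

        Returns True when any of the three quantities is missing (nothing
        to check) or when the identity holds within ``n_sd`` combined
        standard deviations (floored at 0.05 decades for rounded tables).
        """
        if None in (self.binding_energy, self.log10_binding_rate, self.log10_unbinding_rate):
            return True
        lhs = self.binding_energy / _LN10
        rhs = self.log10_binding_rate - self.log10_unbinding_rate
        sd = math.hypot(
            self.uncertainties.get("binding_energy", 0.0) / _LN10,
            self.uncertainties.get("log10_binding_rate", 0.0),
            self.uncertainties.get("log10_unbinding_rate", 0.0),
        )
        return abs(lhs - rhs) <= max(n_sd * sd, 0.05)


@dataclass(frozen=True)
class CorrectedBinding:
    """Bimolecular (tether-free) binding parameters derived from a tethered
    measurement and the tether geometry."""

    effective_concentration: float  # c_bar, mol/L
    correction_energy: float  # dEc, kBT
    bimolecular_energy: Optional[float] = None  # E_on, kBT
    log10_bimolecular_rate: Optional[float] = None  # log10(k_on / M^-1 s^-1)
    log10_unbinding_rate: Optional[float] = None  # carried through unchanged
    bimolecular_constant: Optional[float] = None  # K_on, M^-1
    condition: Mapping[str, object] = field(default_factory=dict)
    uncertainties: Mapping[str, float] = field(default_factory=dict)
    frame: str = "bimolecular"


def correction_energy(
    tether: GaussianTether, constants: Constants = DEFAULT_CONSTANTS
) -> float:
    """Tether correction energy dEc = -ln(c_bar / 1 M), in kBT."""
    return -math.log(average_effective_concentration(tether, constants))


def correct_measurement(
    meas: TetheredBindingMeasurement,
    tether: GaussianTether,
    constants: Constants = DEFAULT_CONSTANTS,
) -> CorrectedBinding:
    """Convert a tethered measurement into bimolecular quantities.

    Uncertainties propagate unchanged through the purely additive
    (energy) and multiplicative (rate) corrections; the unbinding rate is
    carried through untouched.
    """
    if meas.frame != "tethered":
        raise ValueError(
            f"measurement frame is {meas.frame!r}; correction applies only to "
            "tethered records (refusing to correct twice)"
        )
    if meas.binding_energy is None and meas.log10_binding_rate is None:
        raise ValueError("nothing to correct: need binding_energy or log10_binding_rate")
    c_bar = average_effective_concentration(tether, constants)
    d_ec = -math.log(c_bar)
    e_on = None if meas.binding_energy is None else meas.binding_energy + d_ec
    log_kon = (
        None
        if meas.log10_binding_rate is None
        else meas.log10_binding_rate - math.log10(c_bar)
    )
    k_on_const = None
    if meas.log10_binding_rate is not None and meas.log10_unbinding_rate is not None:
        k_on_const = 10.0 ** (log_kon - meas.log10_unbinding_rate)
    unc = dict(meas.uncertainties)
    if "binding_energy" in unc:
        unc["bimolecular_energy"] = unc["binding_energy"]
    if "log10_binding_rate" in unc:
        unc["log10_bimolecular_rate"] = unc["log10_binding_rate"]
    return CorrectedBinding(
        effective_concentration=c_bar,
        correction_energy=d_ec,
        bimolecular_energy=e_on,
        log10_bimolecular_rate=log_kon,
        log10_unbinding_rate=meas.log10_unbinding_rate,
        bimolecular_constant=k_on_const,
        condition=dict(meas.condition),
        uncertainties=unc,
    )


def coupling_concentration(
    linker_aa: Optional[int] = None,
    h: float = 0.0,
    constants: Constants = DEFAULT_CONSTANTS,
    contour_length: Optional[float] = None,
    area_per_lipid: float = 0.7,
) -> float:
    """Effective concentration of one tandem domain at the membrane while its
    partner is bound, in mol/L.

    The inter-domain linker is a Gaussian chain of ``linker_aa`` residues
    (or an explicit ``contour_length`` in nm) with height gap ``h`` (default
    0: both domains sit on the membrane).
    """
    if contour_length is None:
        if linker_aa is None or linker_aa <= 0:
            raise ValueError("need linker_aa > 0 or an explicit contour_length")
        contour_length = linker_aa * CONTOUR_PER_AA
    tether = GaussianTether(
        PEPTIDE_PERSISTENCE,
        contour_length,
        anchor_height=max(h, 0.0),
        binding_height=max(-h, 0.0),
        area_per_lipid=area_per_lipid,
    )
    return average_effective_concentration(tether, constants)


@dataclass(frozen=True)
class TandemDecomposition:
    """Decomposition of a tandem-domain binding energy into its parts,
    E_AB = E_A + E_B + coupling (all bimolecular, kBT)."""

    tandem_energy: float
    domain_a_energy: float
    domain_b_energy: float
    coupling_energy: float
    coupling_concentration: float  # mol/L
    uncertainty: Optional[float] = None  # on domain_a_energy, kBT


def decompose_tandem(
    tandem_energy: float,
    domain_b_energy: float,
    linker_aa: Optional[int] = None,
    constants: Constants = DEFAULT_CONSTANTS,
    contour_length: Optional[float] = None,
    h: float = 0.0,
    tandem_sd: Optional[float] = None,
    domain_b_sd: Optional[float] = None,
) -> TandemDecomposition:
    """Solve E_A = E_AB - E_B - ln(c / 1 M) for the unmeasured domain.

    Inputs must be tether-corrected (bimolecular) energies.  Uncertainties,
    when supplied, combine in quadrature (the deterministic coupling term
    contributes none).
    """
    c = coupling_concentration(linker_aa, h, constants, contour_length)
    if not c > 0:
        raise ValueError("coupling concentration must be positive")
    coupling = math.log(c)
    e_a = tandem_energy - domain_b_energy - coupling
    sd = None
    if tandem_sd is not None or domain_b_sd is not None:
        sd = math.hypot(tandem_sd or 0.0, domain_b_sd or 0.0)
    return TandemDecomposition(
        tandem_energy=tandem_energy,
        domain_a_energy=e_a,
        domain_b_energy=domain_b_energy,
        coupling_energy=coupling,
        coupling_concentration=c,
        uncertainty=sd,
    )
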