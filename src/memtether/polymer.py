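"""Worm-like-chain elasticity and Gaussian-chain tether statistics.

Two polymer descriptions are used side by side:

* The Marko--Siggia interpolation of the worm-like chain (WLC) gives the
  force--extension relation of stretched segments (the DNA handle and the
  unfolded polypeptide linker).  The optional ``stretch_modulus`` adds the
  enthalpic term ``F/K`` to the relative extension (extensible WLC).
* A Gaussian chain describes the *unstretched* membrane-anchored linker
  whose free end explores space around the anchor.  Its end-position
  distribution is an isotropic Gaussian with per-axis variance ``2 P L / 3``,
  which yields the effective concentration of a tethered ligand at its
  binding surface and, integrated over the membrane plane, the average
  effective concentration that converts tethered measurements into
  bimolecular ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .constants import DEFAULT_CONSTANTS, Constants

__all__ = [
    "WormLikeChain",
    "GaussianTether",
    "wlc_force",
    "wlc_extension",
    "wlc_stretch_energy",
    "end_density",
    "surface_density",
    "average_effective_concentration",
    "end_fluctuation_sigma",
    "image_corrected_concentration",
    "CONTOUR_PER_AA",
    "PEPTIDE_PERSISTENCE",
]

#: Contour length per amino acid, nm.
CONTOUR_PER_AA = 0.365
#: Persistence length of an unfolded polypeptide, nm.
PEPTIDE_PERSISTENCE = 0.6

_ROOT_RTOL = 1e-9


@dataclass(frozen=True)
class WormLikeChain:
    """Elastic parameters of one stretched polymer segment.

    Parameters
    ----------
    persistence_length:
        P in nm.
    contour_length:
        L in nm.
    stretch_modulus:
        Enthalpic stretch modulus K in pN; ``None`` means inextensible.
    name:
        Optional label used in error messages.
    """

    persistence_length: float
    contour_length: float
    stretch_modulus: Optional[float] = None
    name: str = "chain"

    def __post_init__(self) -> None:
        if not self.persistence_length > 0:
            raise ValueError(f"{self.name}: persistence_length must be > 0")
        if not self.contour_length > 0:
            raise ValueError(f"{self.name}: contour_length must be > 0")
        if self.stretch_modulus is not None and not self.stretch_modulus > 0:
            raise ValueError(f"{self.name}: stretch_modulus must be > 0")

    @classmethod
    def polypeptide(cls, n_aa: int, name: str = "polypeptide") -> "WormLikeChain":
        """Unfolded polypeptide of ``n_aa`` residues (0.365 nm/aa, P = 0.6 nm)."""
        return cls(PEPTIDE_PERSISTENCE, n_aa * CONTOUR_PER_AA, name=name)


def _ms_reduced_force(z: float) -> float:
    """Marko--Siggia interpolation in reduced units (force * P / kBT)."""
    return z + 1.0 / (4.0 * (1.0 - z) ** 2) - 0.25


def _ms_reduced_energy(z: float) -> float:
    """Integral of the reduced Marko--Siggia force from 0 to z (exact)."""
    return z * z / 2.0 + 1.0 / (4.0 * (1.0 - z)) - z / 4.0 - 0.25


def wlc_force(
    chain: WormLikeChain, extension: float, constants: Constants = DEFAULT_CONSTANTS
) -> float:
    """Tension of a WLC held at a given end-to-end extension, in pN.

    Uses the Marko--Siggia interpolation; when ``stretch_modulus`` is set the
    enthalpic term ``F/K`` is subtracted from the relative extension and the
    relation is solved self-consistently.
    """
    if not np.isfinite(extension) or extension < 0:
        raise ValueError(f"{chain.name}: extension must be finite and >= 0")
    if extension == 0:
        return 0.0
    kbt = constants.thermal_energy
    L, P, K = chain.contour_length, chain.persistence_length, chain.stretch_modulus
    if K is None:
        if extension >= L:
            raise ValueError(
                f"{chain.name}: extension {extension} nm >= contour length {L} nm "
                "for an inextensible chain"
            )
        return (kbt / P) * _ms_reduced_force(extension / L)

    # Extensible: find F with x/L - F/K = z and F = (kBT/P) f(z).
    def resid(f: float) -> float:
        z = extension / L - f / K
        if z >= 1.0:
            return -math.inf
        if z <= 0.0:
            return f
        return f - (kbt / P) * _ms_reduced_force(z)

    hi = 1.0
    while resid(hi) < 0:
        hi *= 2.0
        if hi > 1e9:
            raise ValueError(f"{chain.name}: no force solution at x={extension} nm")
    return brentq(resid, 0.0, hi, rtol=_ROOT_RTOL)


def wlc_extension(
    chain: WormLikeChain, force: float, constants: Constants = DEFAULT_CONSTANTS
) -> float:
    """Extension of a WLC at a given force, in nm (inverse of :func:`wlc_force`)."""
    if not np.isfinite(force):
        raise ValueError(f"{chain.name}: force must be finite")
    if force < 0:
        raise ValueError(f"{chain.name}: force must be >= 0")
    if force == 0:
        return 0.0
    kbt = constants.thermal_energy
    L, P, K = chain.contour_length, chain.persistence_length, chain.stretch_modulus
    fred = force * P / kbt
    z = brentq(lambda zz: _ms_reduced_force(zz) - fred, 0.0, 1.0 - 1e-14, rtol=_ROOT_RTOL)
    if K is not None:
        z += force / K
    return z * L


def wlc_stretch_energy(
    chain: WormLikeChain, force: float, constants: Constants = DEFAULT_CONSTANTS
) -> float:
    """Entropic (plus enthalpic, if extensible) stretching energy in kBT.

    Returns ``integral_0^{x(F)} F(x') dx'``.  For the inextensible chain the
    Marko--Siggia integral has a closed form; the extensible variant is
    evaluated as ``F x(F) - integral_0^F x dF'`` by adaptive quadrature.
    """
    if not np.isfinite(force) or force < 0:
        raise ValueError(f"{chain.name}: force must be finite and >= 0")
    if force == 0:
        return 0.0
    kbt = constants.thermal_energy
    L, P, K = chain.contour_length, chain.persistence_length, chain.stretch_modulus
    if K is None:
        z = wlc_extension(chain, force, constants) / L
        return (L / P) * _ms_reduced_energy(z)
    x_of = lambda f: wlc_extension(chain, f, constants)
    integral, err = quad(x_of, 0.0, force, epsabs=1e-6, epsrel=1e-8, limit=200)
    if err > 1e-4:
        raise RuntimeError(
            f"{chain.name}: stretch-energy quadrature did not converge "
            f"(abs error estimate {err:.2e} nm pN)"
        )
    return (force * x_of(force) - integral) / kbt


@dataclass(frozen=True)
class GaussianTether:
    """Geometry and chain parameters of a membrane-anchored Gaussian linker.

    The linker is anchored at height ``anchor_height`` (h0) above the outer
    membrane surface (z = 0); its free end carries the ligand, which sits at
    height ``binding_height`` (h1) when bound.  ``area_per_lipid`` (s) sets
    the surface density of independent binding sites.
    """

    persistence_length: float
    contour_length: float
    anchor_height: float = 6.0
    binding_height: float = 2.0
    area_per_lipid: float = 0.7

    def __post_init__(self) -> None:
        if not (self.persistence_length > 0 and self.contour_length > 0):
            raise ValueError("persistence_length and contour_length must be > 0")
        if not self.area_per_lipid > 0:
            raise ValueError("area_per_lipid must be > 0")
        if self.anchor_height < 0 or self.binding_height < 0:
            raise ValueError("heights must be >= 0")

    @classmethod
    def from_linker_aa(
        cls,
        n_aa: int,
        anchor_height: float = 6.0,
        binding_height: float = 2.0,
        area_per_lipid: float = 0.7,
    ) -> "GaussianTether":
        """Polypeptide linker of ``n_aa`` residues with the standard geometry."""
        return cls(
            PEPTIDE_PERSISTENCE,
            n_aa * CONTOUR_PER_AA,
            anchor_height,
            binding_height,
            area_per_lipid,
        )

    @property
    def height_gap(self) -> float:
        """h = h0 - h1, the anchor-to-binding-plane height difference in nm."""
        return self.anchor_height - self.binding_height

    @property
    def anchor(self) -> np.ndarray:
        """Anchor point r0 = (0, 0, h0) in nm."""
        return np.array([0.0, 0.0, self.anchor_height])


def end_fluctuation_sigma(tether: GaussianTether) -> float:
    """Per-axis standard deviation of the free-end position, sqrt(2 P L / 3) nm."""
    return math.sqrt(2.0 * tether.persistence_length * tether.contour_length / 3.0)


def end_density(
    tether: GaussianTether,
    point: Sequence[float],
    constants: Constants = DEFAULT_CONSTANTS,
) -> float:
    """Effective concentration of the free chain end at a point, in mol/L.

    Gaussian end-position distribution around the anchor r0 with per-axis
    variance 2 P L / 3, converted from number density (nm^-3) to molarity.
    """
    r = np.asarray(point, dtype=float)
    if r.shape != (3,) or not np.all(np.isfinite(r)):
        raise ValueError("point must be a finite 3-vector (nm)")
    PL = tether.persistence_length * tether.contour_length
    d2 = float(np.sum((r - tether.anchor) ** 2))
    density = (3.0 / (4.0 * math.pi * PL)) ** 1.5 * math.exp(-3.0 * d2 / (4.0 * PL))
    return constants.density_to_molar(density)


def surface_density(
    tether: GaussianTether, rho: float, constants: Constants = DEFAULT_CONSTANTS
) -> float:
    """Effective free-end concentration at radial distance ``rho`` on the
    binding plane z = h1, in mol/L."""
    if rho < 0:
        raise ValueError("rho must be >= 0")
    return end_density(tether, (rho, 0.0, tether.binding_height), constants)


def average_effective_concentration(
    tether: GaussianTether, constants: Constants = DEFAULT_CONSTANTS
) -> float:
    """Average effective concentration of the tethered ligand on the membrane,
    in mol/L (closed form).

    The plane integral of the surface density divided by the area per lipid:
    ``(1 / (s N_A)) (3 / (4 pi P L))^{1/2} exp(-3 h^2 / (4 P L))``.
    """
    PL = tether.persistence_length * tether.contour_length
    h = tether.height_gap
    density = (
        (3.0 / (4.0 * math.pi * PL)) ** 0.5
        * math.exp(-3.0 * h * h / (4.0 * PL))
        / tether.area_per_lipid
    )
    return constants.density_to_molar(density)


def image_corrected_concentration(
    tether: GaussianTether,
    constants: Constants = DEFAULT_CONSTANTS,
    boundary: Literal["absorbing", "reflecting"] = "absorbing",
) -> float:
    """Average effective concentration with an image-method membrane boundary.

    The impenetrable membrane at z = 0 is handled by a mirror source at
    z = -h0: subtracted for an absorbing boundary (chains whose path would
    cross the membrane are removed) or added for a reflecting one.  As
    h0/sigma grows the image term vanishes and the result reduces to the
    unbounded closed form.
    """
    if boundary not in ("absorbing", "reflecting"):
        raise ValueError(f"unrecognized boundary {boundary!r}")
    if not tether.anchor_height > 0:
        raise ValueError("anchor_height must be > 0 for the image construction")
    PL = tether.persistence_length * tether.contour_length
    h = tether.height_gap
    h_image = tether.anchor_height + tether.binding_height
    main = math.exp(-3.0 * h * h / (4.0 * PL))
    image = math.exp(-3.0 * h_image * h_image / (4.0 * PL))
    factor = main - image if boundary == "absorbing" else main + image
    density = (3.0 / (4.0 * math.pi * PL)) ** 0.5 * factor / tether.area_per_lipid
    return constants.density_to_molar(density)
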