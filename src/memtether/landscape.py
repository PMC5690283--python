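"""Force-dependent two-state energy landscape on a contour-length coordinate.

The binding/unbinding reaction is described on a reaction coordinate l, the
contour length of stretched polypeptide linker: l = 0 in the bound state
(the linker is slack), l = L in the unbound state (the full linker is under
tension), and l = l_ts at the unbinding transition state.  The zero-force
state free energies are G(0) = -Eb (bound), G(L) = 0 (unbound reference)
and G(l_ts) = E_ts.  Under a constant force F the tilted potential is

    G~(l, F) = G(l) + E_stretch(l, F) - F x(l, F) / kBT

with E_stretch the worm-like-chain stretching energy of a chain of contour
length l and x(l, F) its extension plus the anchor-height change
``geometry_offset * l / L`` that accrues as the protein detaches from the
membrane.  Unbinding probabilities follow a Boltzmann distribution over the
two wells; binding and unbinding rates follow Kramers' theory with a single
attempt rate k_m:

    P_ub(F)  = 1 / (1 + exp(dG~(F)))
    k_ub(F)  = k_m exp(-(G~(l_ts,F) - G~(0,F)))
    k_b(F)   = k_m exp(-(G~(l_ts,F) - G~(L,F)))

so that k_b/k_ub = exp(-dG~) holds identically (detailed balance).  The
DNA handle and trap potentials are common to both states at fixed force and
cancel in all state differences (isotensional reduction).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit, least_squares

from .constants import DEFAULT_CONSTANTS, Constants
from .polymer import (
    GaussianTether,
    WormLikeChain,
    _ms_reduced_energy,
    _ms_reduced_force,
)

__all__ = [
    "EnergyLandscapeModel",
    "ForceSeries",
    "LandscapeFit",
    "FitConfig",
    "tilted_free_energy",
    "unbinding_probability",
    "rates",
    "predict_extension_change",
    "align_equilibrium_forces",
    "fit_landscape",
]


def _reduced_extension(f_red: np.ndarray) -> np.ndarray:
    """Invert the Marko--Siggia interpolation: relative extension z(f P / kBT)."""
    f_red = np.atleast_1d(np.asarray(f_red, dtype=float))
    out = np.empty_like(f_red)
    for i, f in enumerate(f_red):
        out[i] = 0.0 if f <= 0 else brentq(
            lambda z: _ms_reduced_force(z) - f, 0.0, 1.0 - 1e-14, rtol=1e-12
        )
    return out


@dataclass(frozen=True)
class EnergyLandscapeModel:
    """Zero-force landscape parameters plus the mechanics needed to predict
    force-dependent observables.

    Parameters
    ----------
    binding_energy:
        Eb > 0, depth of the bound state below the unbound reference, kBT.
    barrier_energy:
        E_ts, transition-state free energy above the unbound reference at
        zero force, kBT.
    transition_state_contour:
        l_ts in nm, position of the barrier on the contour-length coordinate.
    attempt_rate:
        Kramers prefactor k_m in s^-1 (shared by both directions).
    linker:
        Membrane-tether geometry (supplies the default geometry offset).
    linker_wlc:
        Elasticity of the fully stretched linker (inextensible WLC).
    geometry_offset:
        Bound-to-unbound anchor-height change in nm, accrued linearly along
        the reaction coordinate; defaults to h0 - h1 of the tether.
    """

    binding_energy: float
    barrier_energy: float
    transition_state_contour: float
    linker: GaussianTether
    linker_wlc: WormLikeChain
    attempt_rate: float = 1e6
    geometry_offset: Optional[float] = None
    constants: Constants = DEFAULT_CONSTANTS

    def __post_init__(self) -> None:
        L = self.linker_wlc.contour_length
        if not 0.0 <= self.transition_state_contour <= L:
            raise ValueError("transition_state_contour must lie in [0, linker contour]")
        if self.linker_wlc.stretch_modulus is not None:
            raise ValueError("landscape linker must be an inextensible WLC")
        if self.geometry_offset is None:
            object.__setattr__(self, "geometry_offset", self.linker.height_gap)

    # -- internal closed-form pieces (z = relative WLC extension at F) ------

    def _station_energies(self, lvals: np.ndarray, z: np.ndarray, force: np.ndarray) -> np.ndarray:
        """Tilted free energy at contour positions ``lvals`` (kBT), vectorized."""
        kbt = self.constants.thermal_energy
        P = self.linker_wlc.persistence_length
        L = self.linker_wlc.contour_length
        g_state = np.interp(
            lvals,
            [0.0, self.transition_state_contour, L],
            [-self.binding_energy, self.barrier_energy, 0.0],
        )
        x = np.where(lvals > 0, z * lvals + self.geometry_offset * lvals / L, 0.0)
        e_stretch = (lvals / P) * _ms_reduced_energy(np.clip(z, 0.0, 1.0 - 1e-14))
        return g_state + e_stretch - force * x / kbt

    def _z(self, force: np.ndarray) -> np.ndarray:
        kbt = self.constants.thermal_energy
        P = self.linker_wlc.persistence_length
        return _reduced_extension(np.asarray(force, dtype=float) * P / kbt)

    # -- public predictions --------------------------------------------------

    def tilted_free_energy(self, contour: float, force: float) -> float:
        """Constant-force tilted potential G~(l, F) in kBT."""
        L = self.linker_wlc.contour_length
        if not 0.0 <= contour <= L:
            raise ValueError(f"contour {contour} nm outside [0, {L}] nm")
        z = self._z([force])
        return float(self._station_energies(np.array([contour]), z, np.asarray([force]))[0])

    def delta_g(self, force) -> np.ndarray:
        """dG~(F) = G~(L, F) - G~(0, F), kBT (unbound minus bound)."""
        force = np.atleast_1d(np.asarray(force, dtype=float))
        z = self._z(force)
        L = self.linker_wlc.contour_length
        g_ub = self._station_energies(np.full_like(force, L), z, force)
        g_b = self._station_energies(np.zeros_like(force), z, force)
        return g_ub - g_b

    def unbinding_probability(self, force) -> np.ndarray:
        """Boltzmann unbinding probability, sigmoidal in force."""
        if np.any(np.asarray(force) < 0):
            raise ValueError("force must be >= 0")
        dg = self.delta_g(force)
        return 1.0 / (1.0 + np.exp(np.clip(dg, -500, 500)))

    def rates(self, force) -> Tuple[np.ndarray, np.ndarray]:
        """Kramers (binding, unbinding) rates in s^-1 at the given force(s)."""
        force = np.atleast_1d(np.asarray(force, dtype=float))
        if np.any(force < 0):
            raise ValueError("force must be >= 0")
        z = self._z(force)
        L = self.linker_wlc.contour_length
        lts = self.transition_state_contour
        g_ts = self._station_energies(np.full_like(force, lts), z, force)
        g_b = self._station_energies(np.zeros_like(force), z, force)
        g_ub = self._station_energies(np.full_like(force, L), z, force)
        if np.any(g_ts < np.maximum(g_b, g_ub)):
            warnings.warn(
                "barrier below a well at some forces; Kramers rates are "
                "extrapolations there",
                RuntimeWarning,
                stacklevel=2,
            )
        k_ub = self.attempt_rate * np.exp(-np.clip(g_ts - g_b, -500, 500))
        k_b = self.attempt_rate * np.exp(-np.clip(g_ts - g_ub, -500, 500))
        return k_b, k_ub

    def predict_extension_change(self, force) -> np.ndarray:
        """Bound-to-unbound extension change dx(F) = x_wlc(L, F) + offset, nm."""
        force = np.atleast_1d(np.asarray(force, dtype=float))
        z = self._z(force)
        return z * self.linker_wlc.contour_length + self.geometry_offset

    def equilibrium_force(self, bracket: Tuple[float, float] = (1e-3, 60.0)) -> float:
        """Force at which dG~ = 0 (P_ub = 0.5), pN."""
        f = lambda F: float(self.delta_g(F)[0])
        lo, hi = bracket
        if f(lo) <= 0:
            return lo
        return brentq(f, lo, hi, rtol=1e-10)

    def transition_state_distance(self, force: Optional[float] = None) -> float:
        """dx_ts = x(l_ts, F) - x(0, F) in nm, by default at the equilibrium force."""
        if force is None:
            force = self.equilibrium_force()
        z = float(self._z([force])[0])
        lts = self.transition_state_contour
        L = self.linker_wlc.contour_length
        return z * lts + self.geometry_offset * lts / L

    def zero_force_log10_rates(self) -> Tuple[float, float]:
        """(log10 k_b, log10 k_ub) at zero force."""
        k_b, k_ub = self.rates(0.0)
        return math.log10(k_b[0]), math.log10(k_ub[0])


# -- module-level functional forms matching the operation names --------------


def tilted_free_energy(model: EnergyLandscapeModel, contour: float, force: float) -> float:
    return model.tilted_free_energy(contour, force)


def unbinding_probability(model: EnergyLandscapeModel, force):
    return model.unbinding_probability(force)


def rates(model: EnergyLandscapeModel, force):
    return model.rates(force)


def predict_extension_change(model: EnergyLandscapeModel, force):
    return model.predict_extension_change(force)


# -- force series and alignment ----------------------------------------------

_SERIES_COLUMNS = ["trap_sep_nm", "force_pN", "p_ub", "k_b_s", "k_ub_s", "dx_nm"]


@dataclass
class ForceSeries:
    """Per-molecule force-dependent observables, one row per trap separation."""

    molecule: str
    data: pd.DataFrame
    force_shift: float = 0.0
    shift_flagged: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in _SERIES_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"force series missing columns {missing}")
        if self.data["trap_sep_nm"].duplicated().any():
            raise ValueError("at most one record per trap separation")
        if not (self.data["force_pN"] > 0).all():
            raise ValueError("forces must be strictly positive")
        if not self.data["p_ub"].between(0, 1).all():
            raise ValueError("probabilities must lie in [0, 1]")
        self.data = self.data.sort_values("force_pN").reset_index(drop=True)


def _logistic_equilibrium_force(force: np.ndarray, p_ub: np.ndarray) -> float:
    """Equilibrium force from a logistic fit of P_ub against force."""
    f0_guess = float(np.interp(0.5, p_ub, force))
    w_guess = max((force.max() - force.min()) / 4.0, 0.05)

    def logistic(F, f0, w):
        return 1.0 / (1.0 + np.exp(-(F - f0) / w))

    try:
        popt, _ = curve_fit(
            logistic, force, p_ub, p0=[f0_guess, w_guess], maxfev=5000
        )
        return float(popt[0])
    except RuntimeError:
        return f0_guess


def align_equilibrium_forces(
    series: Sequence[ForceSeries], force_accuracy: float = 0.10
) -> List[ForceSeries]:
    """Shift each molecule's force axis so all equilibrium forces coincide.

    The per-molecule equilibrium force comes from a logistic interpolation of
    P_ub vs force; each series is translated so that it matches the
    across-molecule mean.  Molecules whose series do not bracket P_ub = 0.5
    are excluded with a warning.  Shifts larger than ``force_accuracy`` times
    the mean equilibrium force (the instrument's absolute-force accuracy) are
    flagged but kept.
    """
    usable, f_eqs = [], []
    for s in series:
        p = s.data["p_ub"].to_numpy()
        if p.min() > 0.5 or p.max() < 0.5:
            warnings.warn(
                f"molecule {s.molecule}: series does not bracket P_ub = 0.5; excluded",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        usable.append(s)
        f_eqs.append(
            _logistic_equilibrium_force(
                s.data["force_pN"].to_numpy(), p
            )
        )
    if not usable:
        raise ValueError("no series brackets P_ub = 0.5; cannot align")
    mean_feq = float(np.mean(f_eqs))
    aligned = []
    for s, feq in zip(usable, f_eqs):
        shift = mean_feq - feq
        data = s.data.copy()
        data["force_pN"] = data["force_pN"] + shift
        for col in ("f_bound_pN", "f_unbound_pN"):
            if col in data.columns:
                data[col] = data[col] + shift
        aligned.append(
            ForceSeries(
                molecule=s.molecule,
                data=data,
                force_shift=shift,
                shift_flagged=abs(shift) > force_accuracy * mean_feq,
            )
        )
    return aligned


# -- joint nonlinear fit -----------------------------------------------------


@dataclass(frozen=True)
class FitConfig:
    """Weights and bootstrap settings for the joint landscape fit.

    ``scale_*`` are the per-block residual normalizations (approximate
    measurement scatter): unbinding probability, log10 rates (decades) and
    extension change (nm).
    """

    scale_p: float = 0.05
    scale_logk: float = 0.10
    scale_dx: float = 0.50
    fit_attempt_rate: bool = False
    n_bootstrap: int = 200
    seed: int = 0
    max_nfev: int = 400


@dataclass
class LandscapeFit:
    """Result of :func:`fit_landscape`."""

    model: EnergyLandscapeModel
    param_sd: dict
    residual_norm: float
    n_points: int
    equilibrium_force: float
    transition_state_distance: float
    log10_k_b0: float
    log10_k_ub0: float
    bootstrap: Optional[pd.DataFrame] = None

    def summary(self) -> dict:
        return {
            "binding_energy_kbt": self.model.binding_energy,
            "barrier_energy_kbt": self.model.barrier_energy,
            "transition_state_contour_nm": self.model.transition_state_contour,
            "attempt_rate_s": self.model.attempt_rate,
            "equilibrium_force_pN": self.equilibrium_force,
            "transition_state_distance_nm": self.transition_state_distance,
            "log10_k_b0": self.log10_k_b0,
            "log10_k_ub0": self.log10_k_ub0,
            "param_sd": self.param_sd,
            "residual_norm": self.residual_norm,
            "n_points": self.n_points,
        }


def _pooled(series: Sequence[ForceSeries]) -> pd.DataFrame:
    frames = []
    for s in series:
        d = s.data.copy()
        d["molecule"] = s.molecule
        frames.append(d)
    return pd.concat(frames, ignore_index=True)


def _fit_once(
    pooled: pd.DataFrame,
    template: EnergyLandscapeModel,
    config: FitConfig,
    x0: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, float]:
    """Weighted joint least squares over {P_ub, log10 k_b, log10 k_ub, dx}."""
    force = pooled["force_pN"].to_numpy(dtype=float)
    obs_p = pooled["p_ub"].to_numpy(dtype=float)
    obs_lkb = np.log10(pooled["k_b_s"].to_numpy(dtype=float))
    obs_lkub = np.log10(pooled["k_ub_s"].to_numpy(dtype=float))
    obs_dx = pooled["dx_nm"].to_numpy(dtype=float)
    # Rates are physically sampled at the state-specific forces of the
    # dumbbell; use them when the series carries them, else the mean force.
    f_b = (
        pooled["f_bound_pN"].to_numpy(dtype=float)
        if "f_bound_pN" in pooled.columns
        else force
    )
    f_u = (
        pooled["f_unbound_pN"].to_numpy(dtype=float)
        if "f_unbound_pN" in pooled.columns
        else force
    )

    kbt = template.constants.thermal_energy
    P = template.linker_wlc.persistence_length
    L = template.linker_wlc.contour_length
    offset = template.geometry_offset
    ln10 = math.log(10.0)
    # forces are fixed during the fit -> precompute the WLC inversions once
    z_m, z_b, z_u = (
        _reduced_extension(f * P / kbt) for f in (force, f_b, f_u)
    )

    def _tilted(lvals, g_state, z, f):
        """G~ at contour lvals with state energy g_state (vectorized)."""
        x = z * lvals + offset * lvals / L
        return g_state + (lvals / P) * _ms_reduced_energy(z) - f * x / kbt

    def stations(params):
        eb, ets, lts = params[:3]
        km = 10.0 ** params[3] if config.fit_attempt_rate else template.attempt_rate
        # barrier crossing out of the bound well happens at the bound-state
        # force; into it at the unbound-state force
        d_ub = _tilted(lts, ets, z_b, f_b) - (-eb)  # G~(lts) - G~(0) at F_b
        d_b = _tilted(lts, ets, z_u, f_u) - _tilted(L, 0.0, z_u, f_u)
        return d_b, d_ub, km

    def residuals(params):
        d_b, d_ub, km = stations(params)
        lkub = np.log10(km) - d_ub / ln10
        lkb = np.log10(km) - d_b / ln10
        # occupancy consistent with the two rates (Boltzmann when F_b = F_u):
        # p_ub = k_ub / (k_ub + k_b) = 1 / (1 + exp(d_ub - d_b))
        dg = d_ub - d_b
        p_ub = 1.0 / (1.0 + np.exp(np.clip(dg, -500, 500)))
        x_full = z_m * L + offset
        return np.concatenate(
            [
                (p_ub - obs_p) / config.scale_p,
                (lkb - obs_lkb) / config.scale_logk,
                (lkub - obs_lkub) / config.scale_logk,
                (x_full - obs_dx) / config.scale_dx,
            ]
        )

    if x0 is None:
        eb0 = max(template.binding_energy, 1.0)
        ets0 = max(template.barrier_energy, 1.0)
        lts0 = min(max(template.transition_state_contour, 0.2), L - 0.2)
        x0 = np.array([eb0, ets0, lts0])
        if config.fit_attempt_rate:
            x0 = np.append(x0, math.log10(template.attempt_rate))
    lo = [0.01, -10.0, 1e-3]
    hi = [60.0, 60.0, L - 1e-3]
    if config.fit_attempt_rate:
        lo.append(2.0)
        hi.append(12.0)
    sol = least_squares(
        residuals, x0, bounds=(lo, hi), max_nfev=config.max_nfev, xtol=1e-12, ftol=1e-12
    )
    if not sol.success and sol.status <= 0:
        raise RuntimeError(f"landscape fit did not converge: {sol.message}")
    return sol.x, float(np.sqrt(np.mean(sol.fun**2)))


def _model_from_params(
    params: np.ndarray, template: EnergyLandscapeModel, config: FitConfig
) -> EnergyLandscapeModel:
    km = 10.0 ** params[3] if config.fit_attempt_rate else template.attempt_rate
    return replace(
        template,
        binding_energy=float(params[0]),
        barrier_energy=float(params[1]),
        transition_state_contour=float(params[2]),
        attempt_rate=float(km),
    )


def fit_landscape(
    series: Sequence[ForceSeries],
    template: EnergyLandscapeModel,
    config: FitConfig = FitConfig(),
    align: bool = True,
) -> LandscapeFit:
    """Fit (Eb, E_ts, l_ts[, k_m]) jointly to force-dependent observables.

    ``series`` holds one :class:`ForceSeries` per molecule; when ``align``
    is true the per-molecule force axes are first translated to a common
    equilibrium force.  Parameter uncertainties come from a bootstrap over
    molecules (resampled with replacement, seed-controlled).
    """
    if align and len(series) > 1:
        series = align_equilibrium_forces(series)
    pooled = _pooled(series)
    if pooled["force_pN"].nunique() < 4:
        raise ValueError("need at least 4 distinct forces for the joint fit")
    best, rnorm = _fit_once(pooled, template, config)
    model = _model_from_params(best, template, config)

    boot_rows = []
    if config.n_bootstrap > 0 and len(series) > 1:
        rng = np.random.default_rng(config.seed)
        mols = list(range(len(series)))
        for _ in range(config.n_bootstrap):
            pick = rng.choice(mols, size=len(mols), replace=True)
            bpool = _pooled([series[i] for i in pick])
            try:
                bp, _ = _fit_once(bpool, template, config, x0=best.copy())
            except RuntimeError:
                continue
            bmodel = _model_from_params(bp, template, config)
            lkb0, lkub0 = bmodel.zero_force_log10_rates()
            boot_rows.append(
                {
                    "binding_energy_kbt": bp[0],
                    "barrier_energy_kbt": bp[1],
                    "transition_state_contour_nm": bp[2],
                    "transition_state_distance_nm": bmodel.transition_state_distance(),
                    "equilibrium_force_pN": bmodel.equilibrium_force(),
                    "log10_k_b0": lkb0,
                    "log10_k_ub0": lkub0,
                }
            )
    boot = pd.DataFrame(boot_rows) if boot_rows else None
    param_sd = (
        {k: float(boot[k].std(ddof=1)) for k in boot.columns} if boot is not None else {}
    )
    lkb0, lkub0 = model.zero_force_log10_rates()
    return LandscapeFit(
        model=model,
        param_sd=param_sd,
        residual_norm=rnorm,
        n_points=len(pooled),
        equilibrium_force=model.equilibrium_force(),
        transition_state_distance=model.transition_state_distance(),
        log10_k_b0=lkb0,
        log10_k_ub0=lkub0,
        bootstrap=boot,
    )
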