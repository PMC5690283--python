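"""Synthetic dual-trap pulling data with known ground truth.

The generator reproduces the statistical structure the analysis assumes,
not the instrument's physics: a two-state telegraph process whose rates
come from a ground-truth energy landscape evaluated at the state-specific
force (force balance of the two traps, DNA handle and linker at fixed trap
separation), state-dependent mean extensions from WLC mechanics, and
band-limited bead noise modeled as an Ornstein-Uhlenbeck process whose
amplitude is specified as the post-filter standard deviation at the
default 1.5 ms analysis window.

Every simulated trajectory is returned together with exact per-sample
state labels and the per-state forces, extensions and rates that produced
it, so recovery can be scored without touching the generator again.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq
from scipy.signal import lfilter

from .constants import DEFAULT_CONSTANTS, Constants
from .landscape import EnergyLandscapeModel
from .polymer import WormLikeChain, wlc_extension
from .trajectory import Trajectory

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "UnfoldingEvent",
    "FECResult",
    "default_handle",
    "simulate_constant_separation",
    "separation_for_force",
    "simulate_fec",
    "generate_benchmark_suite",
]

#: Analysis filter window (s) to which ``noise_std`` is referenced.
REF_FILTER_WINDOW = 1.5e-3


def default_handle(n_bp: int = 2260) -> WormLikeChain:
    """Typical DNA handle: 0.34 nm/bp, P = 40 nm, K = 1200 pN."""
    return WormLikeChain(40.0, n_bp * 0.34, stretch_modulus=1200.0, name="DNA handle")


@dataclass(frozen=True)
class UnfoldingEvent:
    """Irreversible unfolding drawn by Bell-rate first passage.

    The hazard k0 exp(F dx / kBT) is switched on inside ``force_range``
    and the event is forced at the upper edge if the domain survives to
    it, so sampled unfolding forces always fall inside the range.
    """

    force_range: Tuple[float, float]  # pN
    contour_gain: float  # nm of polypeptide released
    rate_at_zero: float = 1e-4  # s^-1
    distance: float = 2.0  # nm, transition-state distance


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; ``seed`` is mandatory for stochastic outputs."""

    landscape: Optional[EnergyLandscapeModel]
    seed: int
    trap_stiffness: float = 0.2  # pN/nm per trap
    handle: WormLikeChain = field(default_factory=default_handle)
    sampling_rate: float = 20_000.0
    noise_std: float = 2.5  # nm, post-filter target at REF_FILTER_WINDOW
    noise_correlation_time: float = 5e-5  # s
    duration: float = 20.0  # s, constant-separation runs
    pulling_speed: float = 10.0  # nm/s, force ramps
    noise_factor_unbound: float = 1.0  # per-state variance multiplier
    unfolding_events: Tuple[UnfoldingEvent, ...] = ()

    @property
    def series_stiffness(self) -> float:
        """Stiffness of the two traps in series, pN/nm."""
        return self.trap_stiffness / 2.0

    def raw_noise_std(self) -> float:
        """OU standard deviation before filtering that yields ``noise_std``
        after a boxcar mean over REF_FILTER_WINDOW."""
        dt = 1.0 / self.sampling_rate
        n = max(int(round(REF_FILTER_WINDOW / dt)), 1)
        rho = math.exp(-dt / self.noise_correlation_time)
        if n == 1:
            return self.noise_std
        # variance of the mean of n consecutive AR(1) samples
        s = n * (1 + rho) / (1 - rho) - 2 * rho * (1 - rho**n) / (1 - rho) ** 2
        ratio = s / n**2
        return self.noise_std / math.sqrt(ratio)


@dataclass
class GroundTruth:
    """Exact generating quantities for one constant-separation trajectory."""

    labels: np.ndarray  # 0 bound / 1 unbound per raw sample
    force_bound: float
    force_unbound: float
    extension_bound: float
    extension_unbound: float
    k_b: float  # s^-1, evaluated at the unbound-state force
    k_ub: float  # s^-1, evaluated at the bound-state force
    occupancy_unbound: float  # expected, k_ub/(k_b + k_ub)
    occupancy_empirical: float
    n_transitions: int

    @property
    def extension_change(self) -> float:
        return self.extension_unbound - self.extension_bound

    def to_dict(self) -> dict:
        return {
            k: (float(v) if not isinstance(v, np.ndarray) else None)
            for k, v in self.__dict__.items()
            if k != "labels"
        } | {
            "extension_change": float(self.extension_change),
            "n_samples": int(self.labels.size),
        }


def _state_extension(
    config: SimulationConfig, force: float, unbound: bool, extra_contour: float = 0.0
) -> float:
    """Tether extension (handle + stretched polypeptide + geometry) at force."""
    x = wlc_extension(config.handle, force, config.landscape.constants
                      if config.landscape else DEFAULT_CONSTANTS)
    model = config.landscape
    if model is not None and unbound:
        x += wlc_extension(model.linker_wlc, force, model.constants) + model.geometry_offset
    if extra_contour > 0:
        chain = WormLikeChain(0.6, extra_contour, name="unfolded polypeptide")
        consts = model.constants if model else DEFAULT_CONSTANTS
        x += wlc_extension(chain, force, consts)
    return x


def _solve_force(
    config: SimulationConfig,
    separation: float,
    unbound: bool,
    extra_contour: float = 0.0,
) -> float:
    """Force balancing traps, handle and linker at a fixed trap separation."""

    def resid(f: float) -> float:
        return (
            _state_extension(config, f, unbound, extra_contour)
            + f / config.series_stiffness
            - separation
        )

    lo, hi = 1e-9, 200.0
    if resid(lo) > 0 or resid(hi) < 0:
        raise ValueError(
            f"no force-balance solution at separation {separation:.2f} nm"
        )
    return brentq(resid, lo, hi, xtol=1e-9, rtol=1e-12)


def separation_for_force(config: SimulationConfig, force: float) -> float:
    """Trap separation at which the two state forces straddle ``force``."""
    x_b = _state_extension(config, force, unbound=False)
    x_u = _state_extension(config, force, unbound=True)
    return 0.5 * (x_b + x_u) + force / config.series_stiffness


def _gillespie_labels(
    rng: np.random.Generator,
    k_to_unbound: float,
    k_to_bound: float,
    n_samples: int,
    dt: float,
) -> np.ndarray:
    """Exact telegraph path sampled on the acquisition grid."""
    labels = np.empty(n_samples, dtype=np.int8)
    if k_to_unbound <= 0 and k_to_bound <= 0:
        labels[:] = 0
        return labels
    # start from stationary occupancy
    p_ub = k_to_unbound / (k_to_unbound + k_to_bound)
    state = int(rng.random() < p_ub)
    t_end = n_samples * dt
    t = 0.0
    idx = 0
    while t < t_end:
        rate = k_to_unbound if state == 0 else k_to_bound
        dwell = rng.exponential(1.0 / rate) if rate > 0 else t_end - t
        stop = min(int((t + dwell) / dt) + 1, n_samples)
        labels[idx:stop] = state
        idx = stop
        t += dwell
        state ^= 1
        if idx >= n_samples:
            break
    return labels


def _ou_noise(
    rng: np.random.Generator, n: int, sigma: float, tau: float, dt: float
) -> np.ndarray:
    rho = math.exp(-dt / tau)
    innovations = rng.normal(0.0, sigma * math.sqrt(1.0 - rho * rho), size=n)
    x0 = rng.normal(0.0, sigma)
    out = lfilter([1.0], [1.0, -rho], innovations, zi=[rho * x0])[0]
    return out


def simulate_constant_separation(
    config: SimulationConfig,
    trap_separation: float,
    duration: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Trajectory, GroundTruth]:
    """Simulate one extension-time trajectory at a fixed trap separation."""
    if config.landscape is None:
        raise ValueError("constant-separation simulation needs a ground-truth landscape")
    model = config.landscape
    duration = config.duration if duration is None else duration
    rng = np.random.default_rng(config.seed) if rng is None else rng
    dt = 1.0 / config.sampling_rate
    n = int(round(duration * config.sampling_rate))

    f_b = _solve_force(config, trap_separation, unbound=False)
    f_u = _solve_force(config, trap_separation, unbound=True)
    x_b = _state_extension(config, f_b, unbound=False)
    x_u = _state_extension(config, f_u, unbound=True)
    k_ub = float(model.rates(f_b)[1][0])
    k_b = float(model.rates(f_u)[0][0])
    for name, k in (("bound", k_ub), ("unbound", k_b)):
        if k > 0 and 1.0 / k < 10 * dt:
            import warnings

            warnings.warn(
                f"mean {name}-state dwell {1.0 / k:.2e} s < 10 samples at "
                f"separation {trap_separation:.1f} nm",
                RuntimeWarning,
                stacklevel=2,
            )

    labels = _gillespie_labels(rng, k_ub, k_b, n, dt)
    noise = _ou_noise(rng, n, config.raw_noise_std(), config.noise_correlation_time, dt)
    if config.noise_factor_unbound != 1.0:
        noise = noise * np.where(labels == 1, config.noise_factor_unbound, 1.0)
    extension = np.where(labels == 1, x_u, x_b) + noise
    force = np.where(labels == 1, f_u, f_b) - config.series_stiffness * noise
    traj = Trajectory(
        time=np.arange(n) * dt,
        extension=extension,
        force=force,
        sampling_rate=config.sampling_rate,
        trap_separation=trap_separation,
        metadata={"seed": config.seed, "ground_truth": True},
    )
    n_trans = int(np.count_nonzero(np.diff(labels)))
    truth = GroundTruth(
        labels=labels,
        force_bound=f_b,
        force_unbound=f_u,
        extension_bound=x_b,
        extension_unbound=x_u,
        k_b=k_b,
        k_ub=k_ub,
        occupancy_unbound=k_ub / (k_ub + k_b) if (k_ub + k_b) > 0 else 0.0,
        occupancy_empirical=float(np.mean(labels == 1)),
        n_transitions=n_trans,
    )
    return traj, truth


@dataclass
class FECResult:
    """Force-extension curve from a constant-speed separation ramp."""

    time: np.ndarray
    separation: np.ndarray
    extension: np.ndarray
    force: np.ndarray
    labels: np.ndarray  # binding state per sample (0 bound / 1 unbound)
    events: List[dict]  # every transition/unfolding with time and force


def simulate_fec(
    config: SimulationConfig,
    separation_range: Tuple[float, float],
    rng: Optional[np.random.Generator] = None,
) -> FECResult:
    """Quasi-static separation ramp at ``pulling_speed``.

    Binding/unbinding flicker emerges from the landscape kinetics in the
    low-force window; configured unfolding events add contour length at
    Bell-rate first-passage forces inside their ranges.
    """
    if config.pulling_speed <= 0:
        raise ValueError("pulling_speed must be > 0")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    dt = 1.0 / config.sampling_rate
    d0, d1 = separation_range
    n = int(round(abs(d1 - d0) / config.pulling_speed / dt))
    sep = np.linspace(d0, d1, n)
    model = config.landscape

    def tables(extra: float):
        grid = np.linspace(d0, d1, 200)
        fb = np.array([_solve_force(config, d, False, extra) for d in grid])
        if model is not None:
            fu = np.array([_solve_force(config, d, True, extra) for d in grid])
        else:
            fu = fb
        xb = np.array([_state_extension(config, f, False, extra) for f in fb])
        xu = np.array([_state_extension(config, f, True, extra) for f in fu])
        return grid, fb, fu, xb, xu

    grid, fb_t, fu_t, xb_t, xu_t = tables(0.0)
    extra = 0.0
    pending = list(config.unfolding_events)
    state = 0 if model is not None else 1
    labels = np.empty(n, dtype=np.int8)
    force = np.empty(n)
    ext = np.empty(n)
    events: List[dict] = []
    for i in range(n):
        d = sep[i]
        f_b = np.interp(d, grid, fb_t)
        f_u = np.interp(d, grid, fu_t)
        f_now = f_b if state == 0 else f_u
        if model is not None:
            if state == 0:
                k = float(model.rates(f_b)[1][0])
            else:
                k = float(model.rates(f_u)[0][0])
            if rng.random() < -math.expm1(-k * dt):
                state ^= 1
                events.append(
                    {
                        "time_s": i * dt,
                        "force_pN": float(f_b if state == 1 else f_u),
                        "kind": "unbinding" if state == 1 else "binding",
                    }
                )
        still_pending = []
        for ev in pending:
            lo, hi = ev.force_range
            fired = False
            if f_now >= hi:
                fired = True
            elif f_now >= lo:
                kbt = (model.constants if model else DEFAULT_CONSTANTS).thermal_energy
                haz = ev.rate_at_zero * math.exp(f_now * ev.distance / kbt)
                fired = rng.random() < -math.expm1(-haz * dt)
            if fired:
                extra += ev.contour_gain
                events.append(
                    {
                        "time_s": i * dt,
                        # first passage truncated at the range top
                        "force_pN": float(min(f_now, hi)),
                        "kind": "unfolding",
                    }
                )
                grid, fb_t, fu_t, xb_t, xu_t = tables(extra)
            else:
                still_pending.append(ev)
        pending = still_pending
        labels[i] = state
        if state == 0:
            force[i] = np.interp(d, grid, fb_t)
            ext[i] = np.interp(force[i], fb_t, xb_t)
        else:
            force[i] = np.interp(d, grid, fu_t)
            ext[i] = np.interp(force[i], fu_t, xu_t)
    noise = _ou_noise(rng, n, config.raw_noise_std(), config.noise_correlation_time, dt)
    ext = ext + noise
    force = force - config.series_stiffness * noise
    return FECResult(
        time=np.arange(n) * dt,
        separation=sep,
        extension=ext,
        force=force,
        labels=labels,
        events=events,
    )


# -- benchmark suite ---------------------------------------------------------


#: Fastest rate (s^-1) the benchmark aims to keep resolvable at the default
#: analysis bandwidth (mean dwell >= ~5 filter windows of 1.5 ms).
RATE_CAP = 120.0


def _occupancy_grid(
    model: EnergyLandscapeModel, n_sep: int, rate_cap: float = RATE_CAP
) -> np.ndarray:
    """Unbinding-probability targets spanning the transition while keeping
    both mean dwell times resolvable (rates below ``rate_cap``)."""

    def force_at(p: float) -> float:
        dg = math.log((1 - p) / p)
        return brentq(lambda F: float(model.delta_g(F)[0]) - dg, 1e-3, 60.0, rtol=1e-10)

    lo, hi = 0.10, 0.90
    while lo < 0.45 and model.rates(force_at(lo))[0][0] > rate_cap:
        lo += 0.01
    while hi > 0.55 and model.rates(force_at(hi))[1][0] > rate_cap:
        hi -= 0.01
    return np.linspace(lo, hi, n_sep)


def generate_benchmark_suite(
    out_dir,
    seed: int,
    constructs: Optional[Dict[str, EnergyLandscapeModel]] = None,
    n_molecules: int = 5,
    n_separations: int = 6,
    durations: Optional[Dict[str, float]] = None,
    noise_std: float = 2.5,
    overwrite: bool = False,
) -> dict:
    """Write a seeded benchmark of trajectories plus a ground-truth manifest.

    Four reference constructs (unless overridden) x ``n_molecules`` x
    ``n_separations`` trajectories, with separations spanning unbinding
    probabilities 0.1-0.9 of each ground-truth landscape.  Deterministic
    given ``seed``: each trajectory uses its own counter-based substream
    keyed by (construct, molecule, separation).
    """
    from .datasets import reference_landscapes, DEFAULT_DURATIONS
    from .io import write_trajectory

    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)
    constructs = reference_landscapes() if constructs is None else constructs
    durations = dict(DEFAULT_DURATIONS) if durations is None else durations

    manifest = {"seed": seed, "noise_std_nm": noise_std, "constructs": {}, "files": []}
    for ci, (name, model) in enumerate(sorted(constructs.items())):
        config = SimulationConfig(landscape=model, seed=seed, noise_std=noise_std)
        f_eq = model.equilibrium_force()
        lkb0, lkub0 = model.zero_force_log10_rates()
        manifest["constructs"][name] = {
            "binding_energy_kbt": model.binding_energy,
            "barrier_energy_kbt": model.barrier_energy,
            "transition_state_contour_nm": model.transition_state_contour,
            "transition_state_distance_nm": model.transition_state_distance(),
            "attempt_rate_s": model.attempt_rate,
            "equilibrium_force_pN": f_eq,
            "log10_k_b0": lkb0,
            "log10_k_ub0": lkub0,
            "linker_contour_nm": model.linker_wlc.contour_length,
            "geometry_offset_nm": model.geometry_offset,
            "trap_stiffness_pN_nm": config.trap_stiffness,
            "handle_contour_nm": config.handle.contour_length,
            "handle_persistence_nm": config.handle.persistence_length,
            "handle_stretch_modulus_pN": config.handle.stretch_modulus,
        }
        # separations spanning the transition at resolvable rates
        targets = _occupancy_grid(model, n_separations)
        seps = []
        for p in targets:
            dg = math.log((1 - p) / p)
            f = brentq(
                lambda F: float(model.delta_g(F)[0]) - dg, 1e-3, 60.0, rtol=1e-10
            )
            seps.append(separation_for_force(config, f))
        dur = durations.get(name, 20.0)
        for mi in range(n_molecules):
            for si, sep in enumerate(seps):
                ss = np.random.SeedSequence(entropy=seed, spawn_key=(ci, mi, si))
                rng = np.random.default_rng(ss)
                traj, truth = simulate_constant_separation(
                    config, sep, duration=dur, rng=rng
                )
                fname = f"{name.replace(' ', '_')}_m{mi:02d}_s{si:02d}.csv"
                traj.metadata.update(
                    construct=name, molecule=f"m{mi:02d}", separation_index=si
                )
                write_trajectory(out / fname, traj)
                manifest["files"].append(
                    {
                        "file": fname,
                        "construct": name,
                        "molecule": f"m{mi:02d}",
                        "trap_separation_nm": float(sep),
                        "duration_s": dur,
                        "ground_truth": truth.to_dict(),
                    }
                )
    payload = json.dumps(manifest, indent=1, sort_keys=True)
    manifest_path.write_text(payload)
    return manifest
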