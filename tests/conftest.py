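"""Shared fixtures: small analytic objects plus one session-scoped
benchmark round trip (simulate -> HMM -> landscape fit) reused by the
recovery tests."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Dict, List

import numpy as np
import pytest
from scipy.optimize import brentq

from memtether.constants import DEFAULT_CONSTANTS
from memtether.datasets import DEFAULT_DURATIONS, LINKER_AA, reference_landscapes
from memtether.hmm import fit_two_state_hmm
from memtether.landscape import FitConfig, LandscapeFit, fit_landscape
from memtether.pipeline import HMMPoint, force_series_from_points
from memtether.polymer import GaussianTether
from memtether.synth import (
    SimulationConfig,
    _occupancy_grid,
    separation_for_force,
    simulate_constant_separation,
)
from memtether.trajectory import mean_filter

SUITE_SEED = 7
FILTER_WINDOW = 1.5e-3


@pytest.fixture(scope="session")
def constants():
    return DEFAULT_CONSTANTS


@pytest.fixture(scope="session")
def linker_tethers() -> Dict[str, GaussianTether]:
    return {name: GaussianTether.from_linker_aa(aa) for name, aa in LINKER_AA.items()}


@pytest.fixture(scope="session")
def ref_models():
    return reference_landscapes()


@dataclass
class RoundTripResult:
    """One construct's benchmark round trip with ground truth attached."""

    model: object  # truth EnergyLandscapeModel
    points: List[HMMPoint]
    truths: list  # GroundTruth per trajectory, aligned with points
    fit: LandscapeFit
    ll_traces: list  # EM log-likelihood traces, one per trajectory


def _run_construct(name: str, model) -> RoundTripResult:
    config = SimulationConfig(landscape=model, seed=SUITE_SEED)
    duration = DEFAULT_DURATIONS[name]
    targets = _occupancy_grid(model, 6)
    seps = []
    for p in targets:
        dg = math.log((1 - p) / p)
        f = brentq(lambda F: float(model.delta_g(F)[0]) - dg, 1e-3, 60.0)
        seps.append(separation_for_force(config, f))
    points, truths, traces = [], [], []
    ci = sorted(LINKER_AA).index(name)
    for mi in range(5):
        for si, sep in enumerate(seps):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=SUITE_SEED, spawn_key=(ci, mi, si))
            )
            traj, truth = simulate_constant_separation(
                config, sep, duration=duration, rng=rng
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_two_state_hmm(
                    mean_filter(traj, FILTER_WINDOW), seed=100 * mi + si
                )
            points.append(
                HMMPoint(
                    molecule=f"m{mi}",
                    trap_separation=sep,
                    force_bound=fit.state_mean_forces[0],
                    force_unbound=fit.state_mean_forces[1],
                    force_mean=fit.state_mean_forces[2],
                    p_ub=fit.unbinding_probability,
                    k_b=fit.k_b,
                    k_ub=fit.k_ub,
                    dx_obs=fit.extension_change,
                )
            )
            truths.append(truth)
            traces.append(fit.log_likelihood_trace)
    series = force_series_from_points(points, config.handle)
    template = replace(
        model,
        binding_energy=8.0,
        barrier_energy=4.0,
        transition_state_contour=min(2.0, model.linker_wlc.contour_length / 3),
    )
    fit = fit_landscape(series, template, FitConfig(n_bootstrap=200, seed=SUITE_SEED))
    return RoundTripResult(
        model=model, points=points, truths=truths, fit=fit, ll_traces=traces
    )


@pytest.fixture(scope="session")
def benchmark_roundtrip(ref_models) -> Dict[str, RoundTripResult]:
    """Seeded four-construct benchmark analyzed end to end (several minutes)."""
    return {name: _run_construct(name, model) for name, model in ref_models.items()}
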