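"""Benchmark round trip: simulate -> HMM -> landscape fit, in memory.

For each of the four reference constructs, generates the seeded
constant-separation benchmark (5 molecules x 6 separations), idealizes
every trajectory with the two-state HMM, assembles per-molecule force
series (with the handle-compliance correction), and fits the joint
Boltzmann/Kramers model with molecule bootstrap.

Writes results/force_series_<construct>.csv and
results/landscape_recovery.csv comparing fits to generator ground truth.
Raw trajectories are not kept (regenerate them with `memtether simulate`
if files are wanted; they are large).
"""

import math
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from memtether.datasets import DEFAULT_DURATIONS, LINKER_AA, reference_landscapes
from memtether.hmm import fit_two_state_hmm
from memtether.io import write_force_series
from memtether.landscape import FitConfig, fit_landscape
from memtether.pipeline import HMMPoint, force_series_from_points
from memtether.synth import (
    SimulationConfig,
    _occupancy_grid,
    separation_for_force,
    simulate_constant_separation,
)
from memtether.trajectory import mean_filter

SEED = 7
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    rows = []
    for ci, (name, model) in enumerate(sorted(reference_landscapes().items())):
        config = SimulationConfig(landscape=model, seed=SEED)
        duration = DEFAULT_DURATIONS[name]
        seps = []
        for p in _occupancy_grid(model, 6):
            dg = math.log((1 - p) / p)
            f = brentq(lambda F: float(model.delta_g(F)[0]) - dg, 1e-3, 60.0)
            seps.append(separation_for_force(config, f))
        points = []
        for mi in range(5):
            for si, sep in enumerate(seps):
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=SEED, spawn_key=(ci, mi, si))
                )
                traj, _ = simulate_constant_separation(config, sep, duration, rng=rng)
                fit = fit_two_state_hmm(mean_filter(traj, 1.5e-3), seed=100 * mi + si)
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
        series = force_series_from_points(points, config.handle)
        write_force_series(OUT / f"force_series_{name.replace(' ', '_')}.csv", series)
        template = replace(
            model, binding_energy=8.0, barrier_energy=4.0,
            transition_state_contour=min(2.0, model.linker_wlc.contour_length / 3),
        )
        fit = fit_landscape(series, template, FitConfig(n_bootstrap=200, seed=SEED))
        lkb0_t, lkub0_t = model.zero_force_log10_rates()
        rows.append(
            {
                "construct": name,
                "linker_aa": LINKER_AA[name],
                "Eb_truth_kbt": model.binding_energy,
                "Eb_fit_kbt": fit.model.binding_energy,
                "Eb_sd_kbt": fit.param_sd.get("binding_energy_kbt"),
                "dxts_truth_nm": model.transition_state_distance(),
                "dxts_fit_nm": fit.transition_state_distance,
                "Feq_truth_pN": model.equilibrium_force(),
                "Feq_fit_pN": fit.equilibrium_force,
                "log10_kb0_truth": lkb0_t,
                "log10_kb0_fit": fit.log10_k_b0,
                "log10_kub0_truth": lkub0_t,
                "log10_kub0_fit": fit.log10_k_ub0,
            }
        )
        r = rows[-1]
        print(
            f"{name:12s} Eb {r['Eb_fit_kbt']:.2f}/{r['Eb_truth_kbt']:.2f} kBT  "
            f"dx_ts {r['dxts_fit_nm']:.2f}/{r['dxts_truth_nm']:.2f} nm  "
            f"F_eq {r['Feq_fit_pN']:.2f}/{r['Feq_truth_pN']:.2f} pN (fit/truth)"
        )
    pd.DataFrame(rows).to_csv(OUT / "landscape_recovery.csv", index=False)
    print(f"\nwrote {OUT / 'landscape_recovery.csv'}")


if __name__ == "__main__":
    main()
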