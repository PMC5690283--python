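"""Boltzmann/Kramers landscape model, force alignment, and the joint fit."""

import math
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from memtether.landscape import (
    EnergyLandscapeModel,
    FitConfig,
    ForceSeries,
    align_equilibrium_forces,
    fit_landscape,
)
from memtether.polymer import (
    GaussianTether,
    WormLikeChain,
    wlc_extension,
    wlc_stretch_energy,
)


@pytest.fixture(scope="module")
def c2ab_model(ref_models):
    return ref_models["E-Syt2 C2AB"]


class TestTiltedFreeEnergy:
    def test_bound_state_at_zero_force_is_minus_eb(self, c2ab_model):
        assert c2ab_model.tilted_free_energy(0.0, 0.0) == pytest.approx(
            -c2ab_model.binding_energy, rel=1e-12
        )

    def test_first_law_identity(self, c2ab_model, constants):
        """dG~(F) = Eb + E_stretch(L, F) - F dx(F): the pulling work splits
        into unbinding energy plus linker stretching entropy."""
        L = c2ab_model.linker_wlc.contour_length
        for force in (1.0, 2.9, 5.0):
            dg = float(c2ab_model.delta_g(force)[0])
            stretch = wlc_stretch_energy(c2ab_model.linker_wlc, force, constants)
            dx = float(c2ab_model.predict_extension_change(force)[0])
            expected = (
                c2ab_model.binding_energy
                + stretch
                - force * dx / constants.thermal_energy
            )
            assert dg == pytest.approx(expected, abs=1e-9)

    def test_tilt_strictly_decreasing_in_force(self, c2ab_model):
        forces = np.linspace(0.1, 10, 60)
        dg = c2ab_model.delta_g(forces)
        assert np.all(np.diff(dg) < 0)

    def test_contour_domain_enforced(self, c2ab_model):
        with pytest.raises(ValueError, match="contour"):
            c2ab_model.tilted_free_energy(-1.0, 2.0)


class TestUnbindingProbability:
    def test_half_at_equilibrium_force(self, c2ab_model):
        f_eq = c2ab_model.equilibrium_force()
        assert float(c2ab_model.unbinding_probability(f_eq)[0]) == pytest.approx(
            0.5, abs=1e-9
        )

    def test_nearly_zero_at_zero_force(self, c2ab_model):
        assert float(c2ab_model.unbinding_probability(0.0)[0]) < 0.01

    def test_sigmoidal_increase(self, c2ab_model):
        p = c2ab_model.unbinding_probability(np.linspace(0, 8, 50))
        assert np.all(np.diff(p) > 0)
        with pytest.raises(ValueError):
            c2ab_model.unbinding_probability(-1.0)


class TestRates:
    def test_detailed_balance_to_machine_precision(self, ref_models):
        """ln(k_b / k_ub) equals the well free-energy gap dG~ = G~(L) - G~(0)
        at every force, for every model (binding favored while the unbound
        well lies higher)."""
        forces = np.linspace(0.0, 10.0, 41)
        for model in ref_models.values():
            k_b, k_ub = model.rates(forces)
            dg = model.delta_g(forces)
            assert np.allclose(np.log(k_b / k_ub), dg, rtol=0, atol=1e-10)

    def test_rates_cross_at_equilibrium(self, c2ab_model):
        f_eq = c2ab_model.equilibrium_force()
        k_b, k_ub = c2ab_model.rates(f_eq)
        assert k_b[0] == pytest.approx(k_ub[0], rel=1e-9)

    def test_equilibrium_rate_near_printed_value(self, c2ab_model):
        """The ground-truth model's equilibrium rate lands near the measured
        ~43 1/s for the fast construct."""
        f_eq = c2ab_model.equilibrium_force()
        assert float(c2ab_model.rates(f_eq)[1][0]) == pytest.approx(43.0, rel=0.2)

    def test_bell_slope_matches_transition_state_distance(self, c2ab_model, constants):
        f_eq = c2ab_model.equilibrium_force()
        df = 0.05
        _, k_lo = c2ab_model.rates(f_eq - df)
        _, k_hi = c2ab_model.rates(f_eq + df)
        slope = (math.log(k_hi[0]) - math.log(k_lo[0])) / (2 * df)
        dx_ts = c2ab_model.transition_state_distance(f_eq)
        assert slope == pytest.approx(dx_ts / constants.thermal_energy, rel=0.10)

    def test_unbinding_less_force_sensitive_than_binding(self, ref_models):
        """Near equilibrium the unbinding rate's log-slope is smaller in
        magnitude than the binding rate's, for all four constructs."""
        for model in ref_models.values():
            f_eq = model.equilibrium_force()
            df = 0.05
            kb_lo, kub_lo = model.rates(f_eq - df)
            kb_hi, kub_hi = model.rates(f_eq + df)
            s_b = abs(math.log(kb_hi[0] / kb_lo[0]))
            s_ub = abs(math.log(kub_hi[0] / kub_lo[0]))
            assert s_ub < s_b

    def test_barrierless_model_flagged(self, c2ab_model):
        sunk = replace(c2ab_model, barrier_energy=-8.0)
        with pytest.warns(RuntimeWarning, match="barrier"):
            k_b, k_ub = sunk.rates(3.0)
        assert np.isfinite(k_b).all() and np.isfinite(k_ub).all()


class TestExtensionChange:
    def test_limits_and_monotonicity(self, c2ab_model, constants):
        dx0 = float(c2ab_model.predict_extension_change(1e-6)[0])
        assert dx0 == pytest.approx(c2ab_model.geometry_offset, abs=1e-3)
        forces = np.linspace(0.2, 15, 40)
        dx = c2ab_model.predict_extension_change(forces)
        assert np.all(np.diff(dx) > 0)
        # 81-aa linker at ~3 pN: relative extension ~0.24 plus the 4 nm offset
        dx3 = float(c2ab_model.predict_extension_change(3.0)[0])
        assert 8.0 < dx3 < 13.0


def _series_from_model(model, forces, molecule="m0", f_shift=0.0):
    """Noise-free observables generated by the model itself."""
    forces = np.asarray(forces, dtype=float)
    k_b, k_ub = model.rates(forces)
    p = model.unbinding_probability(forces)
    dx = model.predict_extension_change(forces)
    return ForceSeries(
        molecule=molecule,
        data=pd.DataFrame(
            {
                "trap_sep_nm": np.arange(len(forces), dtype=float),
                "force_pN": forces + f_shift,
                "p_ub": p,
                "k_b_s": k_b,
                "k_ub_s": k_ub,
                "dx_nm": dx,
            }
        ),
    )


class TestAlignment:
    def test_single_molecule_zero_shift(self, c2ab_model):
        f_eq = c2ab_model.equilibrium_force()
        s = _series_from_model(c2ab_model, np.linspace(f_eq - 1, f_eq + 1, 6))
        aligned = align_equilibrium_forces([s])
        assert aligned[0].force_shift == pytest.approx(0.0, abs=1e-6)

    def test_two_molecules_mean_centered(self, c2ab_model):
        f_eq = c2ab_model.equilibrium_force()
        grid = np.linspace(f_eq - 1, f_eq + 1, 8)
        lo = _series_from_model(c2ab_model, grid, "a", f_shift=2.8 - f_eq)
        hi = _series_from_model(c2ab_model, grid, "b", f_shift=3.0 - f_eq)
        aligned = align_equilibrium_forces([lo, hi])
        assert aligned[0].force_shift == pytest.approx(0.1, abs=1e-3)
        assert aligned[1].force_shift == pytest.approx(-0.1, abs=1e-3)
        # pooled logistic equilibrium force sits at the pre-alignment mean of
        # the per-molecule logistic estimates (exact: alignment translates
        # each identically-shaped curve onto that mean)
        from memtether.landscape import _logistic_equilibrium_force

        per_mol = [
            _logistic_equilibrium_force(
                s.data["force_pN"].to_numpy(), s.data["p_ub"].to_numpy()
            )
            for s in (lo, hi)
        ]
        pooled = pd.concat([a.data for a in aligned]).sort_values("force_pN")
        crossing = _logistic_equilibrium_force(
            pooled["force_pN"].to_numpy(), pooled["p_ub"].to_numpy()
        )
        assert crossing == pytest.approx(np.mean(per_mol), abs=1e-6)

    def test_non_bracketing_series_excluded(self, c2ab_model):
        f_eq = c2ab_model.equilibrium_force()
        good = _series_from_model(c2ab_model, np.linspace(f_eq - 1, f_eq + 1, 6), "g")
        low = _series_from_model(c2ab_model, np.linspace(0.5, f_eq - 1.0, 6), "l")
        with pytest.warns(RuntimeWarning, match="does not bracket"):
            aligned = align_equilibrium_forces([good, low])
        assert [a.molecule for a in aligned] == ["g"]

    def test_large_shift_flagged(self, c2ab_model):
        f_eq = c2ab_model.equilibrium_force()
        grid = np.linspace(f_eq - 1, f_eq + 1, 8)
        a = _series_from_model(c2ab_model, grid, "a", f_shift=-0.5)
        b = _series_from_model(c2ab_model, grid, "b", f_shift=0.5)
        aligned = align_equilibrium_forces([a, b], force_accuracy=0.10)
        assert any(s.shift_flagged for s in aligned)


class TestFitLandscape:
    def test_self_consistency_noise_free(self, ref_models):
        """Series generated by a model are refit to the generating parameters
        within optimizer tolerance."""
        for name, model in ref_models.items():
            f_eq = model.equilibrium_force()
            series = [
                _series_from_model(model, np.linspace(f_eq - 0.8, f_eq + 0.8, 7))
            ]
            template = replace(
                model, binding_energy=6.0, barrier_energy=3.0,
                transition_state_contour=1.5,
            )
            fit = fit_landscape(series, template, FitConfig(n_bootstrap=0), align=False)
            assert fit.model.binding_energy == pytest.approx(
                model.binding_energy, abs=1e-4
            )
            assert fit.model.barrier_energy == pytest.approx(
                model.barrier_energy, abs=1e-4
            )
            assert fit.model.transition_state_contour == pytest.approx(
                model.transition_state_contour, abs=1e-3
            )

    def test_needs_four_distinct_forces(self, c2ab_model):
        series = [_series_from_model(c2ab_model, [2.0, 2.5, 3.0])]
        with pytest.raises(ValueError, match="4 distinct forces"):
            fit_landscape(series, c2ab_model, FitConfig(n_bootstrap=0), align=False)

    def test_equilibrium_forces_of_reference_models_bracket_printed(self, ref_models):
        """Model equilibrium forces with the declared geometry fall around the
        measured values (e.g. the slow construct in 5-8 pN around 6.5)."""
        printed = {
            "E-Syt2 C2AB": 2.9,
            "E-Syt2 C2C": 6.5,
            "Syt1 C2AB": 4.7,
            "Syt1 C2B": 3.1,
        }
        feq_c2c = ref_models["E-Syt2 C2C"].equilibrium_force()
        assert 5.0 < feq_c2c < 8.0
        for name, model in ref_models.items():
            assert model.equilibrium_force() == pytest.approx(printed[name], abs=1.5)
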