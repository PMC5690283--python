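"""Worm-like-chain mechanics and Gaussian-tether statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from memtether.constants import Constants
from memtether.polymer import (
    CONTOUR_PER_AA,
    GaussianTether,
    WormLikeChain,
    average_effective_concentration,
    end_density,
    end_fluctuation_sigma,
    image_corrected_concentration,
    surface_density,
    wlc_extension,
    wlc_force,
    wlc_stretch_energy,
)

LINKERS = {81: None, 40: None, 73: None, 66: None}


def _grid_inversion_extension(chain, force, constants, n=200_001):
    """Independent oracle: dense-grid evaluation of the interpolation formula,
    inverted by linear interpolation."""
    z = np.linspace(0.0, 1.0 - 1e-6, n)
    f = (constants.thermal_energy / chain.persistence_length) * (
        z + 1.0 / (4.0 * (1.0 - z) ** 2) - 0.25
    )
    return float(np.interp(force, f, z)) * chain.contour_length


class TestWLCForceExtension:
    def test_relaxed_chain_is_tensionless(self, constants):
        chain = WormLikeChain(0.6, 29.565)
        assert wlc_force(chain, 0.0, constants) == 0.0
        assert wlc_extension(chain, 0.0, constants) == 0.0

    def test_peptide_linker_relative_extension_matches_grid_oracle(self, constants):
        """An 81-aa polypeptide at 2.9 pN sits near a quarter of its contour."""
        chain = WormLikeChain(0.6, 81 * CONTOUR_PER_AA)
        x = wlc_extension(chain, 2.9, constants)
        x_oracle = _grid_inversion_extension(chain, 2.9, constants)
        assert x == pytest.approx(x_oracle, abs=1e-3)
        assert x / chain.contour_length == pytest.approx(0.24, abs=0.01)

    def test_force_is_intensive_in_relative_extension(self, constants):
        chain = WormLikeChain(0.6, 20.0)
        doubled = WormLikeChain(0.6, 40.0)
        for z in (0.1, 0.5, 0.9):
            assert wlc_force(chain, z * 20.0, constants) == pytest.approx(
                wlc_force(doubled, z * 40.0, constants), rel=1e-12
            )

    def test_force_strictly_increasing_and_asymptotes_to_contour(self, constants):
        chain = WormLikeChain(1.0, 50.0)
        xs = np.linspace(0, 49.9, 200)
        fs = [wlc_force(chain, x, constants) for x in xs]
        assert np.all(np.diff(fs) > 0)
        exts = [wlc_extension(chain, f, constants) for f in (10, 1000, 100_000)]
        assert np.all(np.diff(exts) > 0)
        assert exts[-1] < chain.contour_length
        # high-force asymptote z ~ 1 - sqrt(kBT / 4 F P)
        assert exts[-1] > (1 - math.sqrt(constants.thermal_energy / 4e5)) * 0.999 * 50

    def test_extension_beyond_contour_rejected(self, constants):
        chain = WormLikeChain(0.6, 10.0, name="short linker")
        with pytest.raises(ValueError, match="short linker"):
            wlc_force(chain, 10.0, constants)
        with pytest.raises(ValueError):
            wlc_extension(chain, float("nan"), constants)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        p=st.floats(0.3, 50.0),
        length=st.floats(5.0, 1000.0),
        force=st.floats(0.01, 60.0),
        extensible=st.booleans(),
    )
    def test_round_trip_closes(self, p, length, force, extensible):
        """force(extension(F)) returns F to 1e-6 pN, extensible or not."""
        chain = WormLikeChain(p, length, stretch_modulus=1200.0 if extensible else None)
        constants = Constants()
        x = wlc_extension(chain, force, constants)
        assert wlc_force(chain, x, constants) == pytest.approx(force, abs=1e-6)


class TestStretchEnergy:
    def test_zero_at_zero_force_then_increasing(self, constants):
        chain = WormLikeChain(0.6, 29.565)
        assert wlc_stretch_energy(chain, 0.0, constants) == 0.0
        energies = [wlc_stretch_energy(chain, f, constants) for f in (1, 2, 5, 10)]
        assert np.all(np.diff(energies) > 0) and energies[0] > 0

    @pytest.mark.parametrize("stretch_modulus", [None, 1200.0])
    def test_matches_dense_trapezoid_integration(self, constants, stretch_modulus):
        chain = WormLikeChain(0.6, 29.565, stretch_modulus=stretch_modulus)
        force = 5.0
        x_end = wlc_extension(chain, force, constants)
        xs = np.linspace(0, x_end, 10_001)
        fs = np.array([wlc_force(chain, x, constants) for x in xs])
        oracle = np.trapezoid(fs, xs) / constants.thermal_energy
        assert wlc_stretch_energy(chain, force, constants) == pytest.approx(
            oracle, abs=1e-4
        )

    def test_low_force_limit_is_hookean(self, constants):
        """Below F P / kBT ~ 0.05 the chain behaves as a spring of stiffness
        3 kBT / (2 P L)."""
        chain = WormLikeChain(0.6, 29.565)
        force = 0.04 * constants.thermal_energy / chain.persistence_length
        k_spring = 3.0 * constants.thermal_energy / (
            2.0 * chain.persistence_length * chain.contour_length
        )
        x = wlc_extension(chain, force, constants)
        hookean = 0.5 * k_spring * x**2 / constants.thermal_energy
        assert wlc_stretch_energy(chain, force, constants) == pytest.approx(
            hookean, rel=0.05
        )


class TestEndDensity:
    def test_peak_value_at_anchor(self, constants):
        t = GaussianTether.from_linker_aa(81)
        peak = end_density(t, t.anchor, constants)
        expected = constants.molar_conversion * (
            3.0 / (4.0 * math.pi * t.persistence_length * t.contour_length)
        ) ** 1.5
        assert peak == pytest.approx(expected, rel=1e-12)
        assert end_density(t, (500.0, 0, 6.0), constants) < 1e-30 * peak

    def test_matches_monte_carlo_chain_sampling(self, constants):
        """Box-counted end positions of simulated Gaussian chains agree with
        the analytic density within 3 standard errors at random points."""
        t = GaussianTether.from_linker_aa(40)
        sigma = end_fluctuation_sigma(t)
        rng = np.random.default_rng(11)
        n = 2_000_000
        ends = rng.normal(0.0, sigma, size=(n, 3)) + t.anchor
        half = 0.5
        points = rng.normal(0.0, sigma, size=(20, 3)) + t.anchor
        for pt in points:
            inside = np.all(np.abs(ends - pt) < half, axis=1)
            count = int(inside.sum())
            # exact box mass from per-axis normal CDFs
            p_box = np.prod(
                [
                    norm.cdf((pt[i] + half - t.anchor[i]) / sigma)
                    - norm.cdf((pt[i] - half - t.anchor[i]) / sigma)
                    for i in range(3)
                ]
            )
            se = math.sqrt(max(n * p_box * (1 - p_box), 1.0))
            assert abs(count - n * p_box) < 3.5 * se
        # and the analytic density integrates to the same box mass at the peak
        mass = quad(
            lambda z: norm.pdf(z, t.anchor_height, sigma), t.anchor_height - half,
            t.anchor_height + half,
        )[0] * (norm.cdf(half / sigma) - norm.cdf(-half / sigma)) ** 2
        center_density = end_density(t, t.anchor, constants) / constants.molar_conversion
        assert mass == pytest.approx(
            center_density * (2 * half) ** 3, rel=0.05
        )


class TestSurfaceDensity:
    def test_equals_end_density_on_binding_plane(self, constants):
        t = GaussianTether.from_linker_aa(73)
        rng = np.random.default_rng(3)
        for rho in rng.uniform(0, 10, size=50):
            assert surface_density(t, rho, constants) == pytest.approx(
                end_density(t, (rho, 0.0, t.binding_height), constants), rel=1e-12
            )
        with pytest.raises(ValueError):
            surface_density(t, -1.0, constants)

    def test_gaussian_in_radius_with_slope_minus_3_over_4PL(self, constants):
        t = GaussianTether.from_linker_aa(81)
        rho = np.linspace(0.5, 6.0, 40)
        logc = np.log([surface_density(t, r, constants) for r in rho])
        slope = np.polyfit(rho**2, logc, 1)[0]
        expected = -3.0 / (4.0 * t.persistence_length * t.contour_length)
        assert slope == pytest.approx(expected, rel=1e-9)

    def test_zero_height_gap_peak(self, constants):
        t = GaussianTether(0.6, 4.7, anchor_height=2.0, binding_height=2.0)
        peak = (3.0 / (4.0 * math.pi * 0.6 * 4.7)) ** 1.5 * constants.molar_conversion
        assert surface_density(t, 0.0, constants) == pytest.approx(peak, rel=1e-12)


class TestAverageEffectiveConcentration:
    @pytest.mark.parametrize(
        "aa, printed", [(81, 0.14), (40, 0.10), (73, 0.14), (66, 0.13)]
    )
    def test_reproduces_printed_concentrations(self, constants, aa, printed):
        c = average_effective_concentration(GaussianTether.from_linker_aa(aa), constants)
        assert round(c, 2) == printed

    def test_matches_plane_quadrature_of_surface_density(self, constants):
        """2-D integral of the surface density over the membrane divided by
        the area per lipid reproduces the closed form to 0.1%."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            t = GaussianTether(
                persistence_length=rng.uniform(0.3, 2.0),
                contour_length=rng.uniform(3.0, 40.0),
                anchor_height=rng.uniform(0.0, 8.0),
                binding_height=rng.uniform(0.0, 4.0),
                area_per_lipid=rng.uniform(0.4, 1.2),
            )
            integral = quad(
                lambda r: 2 * math.pi * r * surface_density(t, r, constants),
                0,
                np.inf,
            )[0]
            closed = average_effective_concentration(t, constants)
            assert integral / t.area_per_lipid == pytest.approx(closed, rel=1e-3)

    def test_decreasing_in_height_gap_and_chain_size(self, constants):
        base = dict(persistence_length=0.6, area_per_lipid=0.7, binding_height=0.0)
        cs = [
            average_effective_concentration(
                GaussianTether(contour_length=10.0, anchor_height=h, **base), constants
            )
            for h in np.linspace(0, 8, 9)
        ]
        assert np.all(np.diff(cs) < 0)
        # decreasing in chain size P*L once the end fluctuation exceeds the
        # height gap (for small chains the exponential term dominates and the
        # trend reverses below L = 3 h^2 / (2 P))
        cs = [
            average_effective_concentration(
                GaussianTether(contour_length=L, anchor_height=1.0, **base), constants
            )
            for L in np.linspace(5, 50, 10)
        ]
        assert np.all(np.diff(cs) < 0)


class TestEndFluctuation:
    def test_forty_aa_linker_sigma(self):
        t = GaussianTether.from_linker_aa(40)
        assert end_fluctuation_sigma(t) == pytest.approx(
            math.sqrt(2 * 0.6 * 14.6 / 3), rel=1e-12
        )
        assert end_fluctuation_sigma(t) == pytest.approx(2.42, abs=0.01)

    def test_scaling(self):
        s1 = end_fluctuation_sigma(GaussianTether(0.6, 10.0))
        s4 = end_fluctuation_sigma(GaussianTether(0.6, 40.0))
        assert s4 == pytest.approx(2 * s1, rel=1e-12)
        assert end_fluctuation_sigma(GaussianTether(1e-9, 10.0)) < 1e-4


class TestImageCorrection:
    def test_reduces_to_closed_form_far_from_membrane(self, constants):
        t = GaussianTether(0.6, 4.0, anchor_height=10.0, binding_height=2.0)
        assert t.anchor_height / end_fluctuation_sigma(t) > 5
        plain = average_effective_concentration(t, constants)
        for boundary in ("absorbing", "reflecting"):
            corrected = image_corrected_concentration(t, constants, boundary)
            assert abs(corrected - plain) / plain < 1e-3

    def test_correction_energy_shift_small_for_all_constructs(self, constants):
        """The membrane boundary changes the correction energies of the four
        anchor linkers by less than 0.2 kBT."""
        for aa in (81, 40, 73, 66):
            t = GaussianTether.from_linker_aa(aa)
            plain = average_effective_concentration(t, constants)
            for boundary in ("absorbing", "reflecting"):
                corrected = image_corrected_concentration(t, constants, boundary)
                assert abs(math.log(corrected / plain)) < 0.2

    def test_matches_bridge_rejection_monte_carlo(self, constants):
        """Absorbing-boundary density at the binding plane equals Gaussian
        sampling with Brownian-bridge crossing rejection, within 3 SE."""
        t = GaussianTether.from_linker_aa(81)
        sigma = end_fluctuation_sigma(t)
        h0, h1 = t.anchor_height, t.binding_height
        rng = np.random.default_rng(17)
        n = 4_000_000
        z = rng.normal(h0, sigma, size=n)
        survive = (z > 0) & (
            rng.random(n) < -np.expm1(-2.0 * h0 * np.clip(z, 0, None) / sigma**2)
        )
        dz = 0.2
        count = int(np.count_nonzero(survive & (np.abs(z - h1) < dz / 2)))
        expected_pdf = norm.pdf(h1, h0, sigma) - norm.pdf(h1, -h0, sigma)
        expect = n * expected_pdf * dz
        assert abs(count - expect) < 3 * math.sqrt(expect)
        # the same image difference underlies the plane-integrated result
        ratio = image_corrected_concentration(
            t, constants, "absorbing"
        ) / average_effective_concentration(t, constants)
        assert ratio == pytest.approx(expected_pdf / norm.pdf(h1, h0, sigma), rel=1e-9)

    def test_unknown_boundary_rejected(self, constants):
        with pytest.raises(ValueError, match="boundary"):
            image_corrected_concentration(
                GaussianTether.from_linker_aa(40), constants, "periodic"
            )
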