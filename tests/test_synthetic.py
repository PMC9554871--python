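"""Forward-model tests: assignments, Lorentzian areas, relaxation
attenuation, noise statistics, and series generators."""

import math

import numpy as np
import pytest

from psiqnmr import (
    AcquisitionParams,
    MultipletAssignment,
    SpeciesComposition,
    default_assignments,
    generate_calibration_series,
    generate_inversion_recovery,
    generate_pegylation_series,
    render_spectrum,
)
from psiqnmr.processing import DEFAULT_WINDOWS, IntegrationWindow, integrate
from psiqnmr.quantify import amine_loading_from_spectrum, integral_table_for
from psiqnmr.relaxometry import fit_inversion_recovery
from psiqnmr.synthetic import internal_standard_umol


def lorentzian_window_area(total_area, center, hwhm, lo, hi):
    """Closed-form integral of an area-normalized Lorentzian over [lo, hi]."""
    return (total_area / math.pi) * (
        math.atan((hi - center) / hwhm) + math.atan((center - lo) / hwhm)
    )


class TestDefaultAssignments:
    def test_alpha_methylene_has_two_protons(self, assignments):
        a = {m.label: m for m in assignments}["a"]
        assert a.n_protons == 2
        assert a.pattern == "complex"
        assert all(2.6 <= c <= 2.8 for c, _ in a.components)

    def test_internal_standard_has_four_aromatic_protons(self, assignments):
        istd = {m.label: m for m in assignments}["IS"]
        assert istd.n_protons == 4
        assert all(7.51 <= c <= 7.64 for c, _ in istd.components)

    def test_peg_peak_overlaps_ethoxy_ch2_window(self):
        labels = {m.label: m for m in default_assignments(include_peg=True)}
        f, d = labels["f"], labels["d"]
        assert 3.70 <= f.center_ppm <= 3.90
        # the ethoxy CH2 sits close enough that a 0.2 ppm window cannot
        # separate the two resonances
        assert abs(f.center_ppm - d.center_ppm) < 0.2

    def test_ethoxy_proton_counts_scale_with_residual_ethoxy(self):
        labels = {m.label: m for m in default_assignments(ethoxy_per_amine=2.0)}
        assert labels["d"].n_protons == 4
        assert labels["e"].n_protons == 6
        none = {m.label for m in default_assignments(ethoxy_per_amine=0.0)}
        assert "d" not in none and "e" not in none

    @pytest.mark.parametrize("pattern,weights", [
        ("triplet", (0.25, 0.5, 0.25)),
        ("quartet", (0.125, 0.375, 0.375, 0.125)),
    ])
    def test_multiplet_weights_are_normalized_binomial(self, pattern, weights):
        m = MultipletAssignment("x", 2.0, pattern, 7.0, 2, "APS-residue", 1.0)
        lines = m.line_positions(400.0)
        assert pytest.approx([w for _, w in lines]) == list(weights)
        # symmetric splitting about the center, spaced by J in ppm
        centers = [c for c, _ in lines]
        assert pytest.approx(np.mean(centers)) == 2.0
        assert pytest.approx(np.diff(centers)) == [7.0 / 400.0] * (len(weights) - 1)


class TestRenderSpectrum:
    def test_empty_sample_is_flat_zero(self, assignments, quiet_acq):
        amounts = {k: 0.0 for k in ("APS-residue", "PEG", "impurity", "internal_standard")}
        s = render_spectrum(assignments, amounts, quiet_acq)
        assert np.all(s.intensity == 0)

    def test_missing_species_error_names_the_species(self, assignments, quiet_acq):
        with pytest.raises(ValueError, match="internal_standard"):
            render_spectrum(assignments, {"APS-residue": 1.0, "impurity": 0.0}, quiet_acq)

    def test_singlet_area_matches_closed_form(self, quiet_acq):
        """Trapezoid area over +/-20 linewidths equals the arctan integral;
        a wide window recovers the full n_protons x amount x n_scans area."""
        m = MultipletAssignment("s", 5.0, "singlet", 0.0, 3, "impurity", 1.0)
        acq = quiet_acq.replace(n_scans=4, relaxation_delay_s=1000.0)
        s = render_spectrum([m], {"impurity": 0.7}, acq)
        fwhm = acq.linewidth_ppm
        lo, hi = 5.0 - 20 * fwhm, 5.0 + 20 * fwhm
        got = integrate(s, IntegrationWindow("s", lo, hi))
        expected_total = 3 * 0.7 * 4
        oracle = lorentzian_window_area(expected_total, 5.0, fwhm / 2, lo, hi)
        assert got == pytest.approx(oracle, rel=1e-2)
        wide = integrate(s, IntegrationWindow("s", 5 - 300 * fwhm, 5 + 300 * fwhm))
        assert wide == pytest.approx(expected_total, rel=1e-2)

    def test_seed_determinism_is_bitwise(self, assignments, amounts):
        acq = AcquisitionParams(noise_sigma=0.01, seed=42)
        s1 = render_spectrum(assignments, amounts, acq)
        s2 = render_spectrum(assignments, amounts, acq)
        assert np.array_equal(s1.intensity, s2.intensity)
        s3 = render_spectrum(assignments, amounts, acq.replace(seed=43))
        assert not np.array_equal(s1.intensity, s3.intensity)

    def test_area_ratio_equals_proton_amount_ratio(self, quiet_acq):
        """At zero noise and full relaxation, area ratios follow
        n_protons x amount exactly (the qNMR premise)."""
        acq = quiet_acq.replace(relaxation_delay_s=5000.0)
        m1 = MultipletAssignment("p", 3.0, "singlet", 0.0, 2, "APS-residue", 1.0)
        m2 = MultipletAssignment("q", 7.0, "singlet", 0.0, 5, "impurity", 1.0)
        s = render_spectrum([m1, m2], {"APS-residue": 0.4, "impurity": 0.9}, acq)
        w = 100 * acq.linewidth_ppm
        a1 = integrate(s, IntegrationWindow("p", 3 - w, 3 + w))
        a2 = integrate(s, IntegrationWindow("q", 7 - w, 7 + w))
        assert a1 / a2 == pytest.approx((2 * 0.4) / (5 * 0.9), rel=2e-3)

    def test_partial_relaxation_attenuates_area(self, quiet_acq):
        """A delay of 5 x T1 recovers 99.33% of the fully relaxed area."""
        m = MultipletAssignment("s", 5.0, "singlet", 0.0, 2, "impurity", 2.0)
        w = IntegrationWindow("s", 4.0, 6.0)
        short = render_spectrum([m], {"impurity": 1.0}, quiet_acq.replace(relaxation_delay_s=10.0))
        full = render_spectrum([m], {"impurity": 1.0}, quiet_acq.replace(relaxation_delay_s=1e4))
        ratio = integrate(short, w) / integrate(full, w)
        assert ratio == pytest.approx(1 - math.exp(-5), abs=1e-4)
        assert abs(ratio - 1) < 0.007


class TestCalibrationSeries:
    def test_fixed_standard_and_linear_analyte(self, composition, quiet_acq):
        series = generate_calibration_series(
            [0.5, 0.75, 1, 1.25, 1.5, 2], composition, 0.4, quiet_acq
        )
        assert len(series) == 6
        # identical standard amount everywhere; only far Lorentzian tails
        # of the mass-dependent peaks vary inside the IS window
        is_areas = [integrate(s, DEFAULT_WINDOWS["IS"]) for _, s in series]
        assert np.allclose(is_areas, is_areas[0], rtol=1e-5)
        # analyte area doubles with mass (constant IS tail adds a ~3e-5
        # relative offset)
        a_half = integrate(series[0][1], DEFAULT_WINDOWS["a"])
        a_one = integrate(series[2][1], DEFAULT_WINDOWS["a"])
        assert a_one == pytest.approx(2 * a_half, rel=1e-4)

    def test_round_trip_recovers_planted_loading(self, composition, quiet_acq):
        series = generate_calibration_series([0.5, 1, 2], composition, 0.4, quiet_acq)
        for mass, spec in series:
            q = amine_loading_from_spectrum(spec, mass)
            assert q.loading_umol_per_mg == pytest.approx(
                composition.amine_loading_umol_per_mg, rel=0.02
            )

    def test_empty_mass_list_rejected(self, composition, quiet_acq):
        with pytest.raises(ValueError, match="empty"):
            generate_calibration_series([], composition, 0.4, quiet_acq)


class TestPegylationSeries:
    def test_planted_peg_sits_in_overlap_window(self, composition, quiet_acq):
        series = generate_pegylation_series(
            [0.1, 2.0], [0.010, 0.025], composition, 0.4, quiet_acq
        )
        table = integral_table_for(series[1][1])
        # the 3.70-3.90 window contains both the PEG peak and the ethoxy CH2
        assert table.normalized["peg"] > table.normalized["e"] * 2 / 3

    def test_ratio_and_loading_lists_must_match(self, composition, quiet_acq):
        with pytest.raises(ValueError, match="equal length"):
            generate_pegylation_series([0.1], [0.01, 0.02], composition, 0.4, quiet_acq)


class TestInversionRecoveryGenerator:
    def test_short_delay_limit_is_b_plus_f(self):
        s = generate_inversion_recovery((1.0, -2.0, 1.0), [1e-9, 1, 2, 3])
        assert s.integrals[0] == pytest.approx(-1.0, abs=1e-8)

    def test_long_delay_asymptote_is_b(self):
        s = generate_inversion_recovery((1.0, -2.0, 1.0), [1, 2, 3, 1e6])
        assert s.integrals[-1] == pytest.approx(1.0)

    def test_nonpositive_delay_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            generate_inversion_recovery((1, -2, 1), [0.0, 1.0, 2.0, 3.0])

    def test_noiseless_series_refits_to_reference_rate(self):
        """Series built from the alpha-methylene reference parameters
        refits to its generating rate constant G = 0.61."""
        from psiqnmr.relaxometry import REFERENCE_IR_PARAMS, STANDARD_IR_DELAYS_S

        s = generate_inversion_recovery(
            REFERENCE_IR_PARAMS["a"], STANDARD_IR_DELAYS_S, 0.0, 0, "a"
        )
        fit = fit_inversion_recovery(s)
        assert fit.G == pytest.approx(0.61, abs=1e-6)


def test_snr_grows_as_sqrt_of_scans(assignments, amounts):
    """Mean S/N quadrupling the scan count doubles, within 10% over 20 seeds."""
    from psiqnmr.processing import estimate_snr
    from psiqnmr.synthetic import noise_sigma_for_snr

    base = AcquisitionParams(n_scans=16)
    sigma = noise_sigma_for_snr(50.0, assignments, amounts, base)
    r1, r4 = [], []
    for seed in range(20):
        s1 = render_spectrum(assignments, amounts, base.replace(noise_sigma=sigma, seed=seed))
        s4 = render_spectrum(
            assignments, amounts, base.replace(n_scans=64, noise_sigma=sigma, seed=seed + 500)
        )
        r1.append(estimate_snr(s1, DEFAULT_WINDOWS["a"]).snr)
        r4.append(estimate_snr(s4, DEFAULT_WINDOWS["a"]).snr)
    assert np.mean(r4) / np.mean(r1) == pytest.approx(2.0, rel=0.10)
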