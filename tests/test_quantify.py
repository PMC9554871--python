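"""Internal-standard quantification, mass calibration, overlap
deconvolution, conjugation metrics, and the count-rate model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psiqnmr import (
    InternalStandard,
    SpeciesComposition,
    count_rate_ratio,
    deconvolve_peg_area,
    elemental_to_loading,
    fit_mass_calibration,
    peg_loading_from_spectrum,
    peg_metrics,
    quantify_by_internal_standard,
)
from psiqnmr.quantify import amine_loading_from_spectrum, integral_table_for
from psiqnmr.synthetic import (
    AcquisitionParams,
    generate_calibration_series,
    generate_pegylation_series,
)

ISTD = InternalStandard()  # 0.4 mg monopotassium phthalate, 4 aromatic H


class TestInternalStandardRelation:
    def test_moles_from_mass(self):
        assert ISTD.moles_umol == pytest.approx(1000 * 0.4 / 204.22)
        assert ISTD.moles_umol == pytest.approx(1.9586, abs=1e-4)

    def test_zero_area_gives_zero_moles(self):
        assert quantify_by_internal_standard(0.0, 2, ISTD) == 0.0

    def test_half_area_on_half_protons(self):
        # area ratio 0.5 on a 2H multiplet against the 4H standard
        got = quantify_by_internal_standard(0.5, 2, ISTD)
        assert got == pytest.approx(0.5 * 2 * 1.9586, abs=2e-4)
        assert got == pytest.approx(ISTD.moles_umol)

    def test_nonpositive_protons_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            quantify_by_internal_standard(1.0, 0, ISTD)


class TestMassCalibration:
    def test_exact_line(self):
        cal = fit_mass_calibration([1, 2, 3], [2, 4, 6])
        assert cal.slope == pytest.approx(2.0)
        assert cal.intercept == pytest.approx(0.0, abs=1e-12)
        assert cal.r_squared == pytest.approx(1.0)

    def test_too_few_distinct_masses_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_mass_calibration([1, 1, 1], [2, 2, 2])

    def test_noiseless_series_recovers_planted_loading(self):
        """Six-mass synthetic series at zero noise: R^2 = 1 and the
        slope-derived loading matches the planted value within 0.5%."""
        comp = SpeciesComposition(amine_loading_umol_per_mg=0.294)
        acq = AcquisitionParams(noise_sigma=0.0)
        series = generate_calibration_series(
            [0.5, 0.75, 1, 1.25, 1.5, 2], comp, 0.4, acq
        )
        areas = [integral_table_for(s).normalized["a"] for _, s in series]
        cal = fit_mass_calibration([m for m, _ in series], areas)
        assert cal.r_squared == pytest.approx(1.0, abs=1e-9)
        assert cal.loading_umol_per_mg == pytest.approx(0.294, rel=0.005)
        assert cal.loading_umol_per_mg_mean == pytest.approx(0.294, rel=0.005)


class TestElemental:
    def test_molar_mass_identity(self):
        assert elemental_to_loading(1.4007) == pytest.approx(1.000, abs=1e-6)

    def test_zero(self):
        assert elemental_to_loading(0.0) == 0.0

    def test_inverse_of_reference_loading(self):
        """0.843 umol/mg corresponds to 1.1808 wt% nitrogen and back."""
        wt = 0.843 * 14.007 / 10.0
        assert wt == pytest.approx(1.1808, abs=1e-4)
        assert elemental_to_loading(wt) == pytest.approx(0.843, rel=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="0, 100"):
            elemental_to_loading(101.0)


class TestDeconvolution:
    def test_two_thirds_rule(self):
        assert deconvolve_peg_area(10.0, 3.0) == pytest.approx(8.0)

    def test_no_ethoxy_leaves_window_area(self):
        assert deconvolve_peg_area(7.5, 0.0) == 7.5

    def test_negative_result_clips_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            assert deconvolve_peg_area(1.0, 3.0) == 0.0

    def test_forward_model_overlap_recovery(self):
        """Planted PEG under a planted ethoxy CH2 overlap is recovered
        within 1% at zero noise for every feeding ratio."""
        comp = SpeciesComposition()
        acq = AcquisitionParams(noise_sigma=0.0)
        planted = [0.010, 0.015, 0.018, 0.025]
        series = generate_pegylation_series([0.1, 0.5, 1, 2], planted, comp, 0.4, acq)
        for (_, spec), expect in zip(series, planted):
            q = peg_loading_from_spectrum(spec, 1.0)
            assert q.moles_umol == pytest.approx(expect, rel=0.01)


class TestConjugationMetrics:
    @pytest.mark.parametrize(
        "n_peg,feed,sub,eff,wt",
        [
            (0.010, 0.1, 3.4, 34.0, 5.0),
            (0.015, 0.5, 5.1, 10.2, 7.5),
            (0.018, 1.0, 6.1, 6.1, 9.0),
            (0.025, 2.0, 8.5, 4.3, 12.5),
        ],
    )
    def test_feeding_ratio_rows(self, n_peg, feed, sub, eff, wt):
        """The four feeding ratios with 0.294 umol amines per mg and 5 kDa
        PEG reproduce the reference percentages at one-decimal precision."""
        m = peg_metrics(n_peg, 0.294, feed, 5000.0, 1.0)
        assert round(m.pct_amine_substituted, 1) == sub
        assert round(m.pct_reaction_efficiency, 1) == eff
        assert round(m.pct_weight, 1) == wt

    def test_zero_peg_gives_zero_metrics(self):
        m = peg_metrics(0.0, 0.294, 1.0)
        assert m.pct_amine_substituted == 0.0
        assert m.pct_reaction_efficiency == 0.0
        assert m.pct_weight == 0.0

    def test_zero_amine_rejected(self):
        with pytest.raises(ValueError, match="n_nh2"):
            peg_metrics(0.01, 0.0, 1.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        n_peg=st.floats(0.0, 10.0),
        n_nh2=st.floats(1e-3, 10.0),
        feed=st.floats(1e-3, 100.0),
    )
    def test_efficiency_times_feed_equals_substitution(self, n_peg, n_nh2, feed):
        m = peg_metrics(n_peg, n_nh2, feed)
        assert m.pct_reaction_efficiency * feed == pytest.approx(
            m.pct_amine_substituted, rel=1e-9, abs=1e-12
        )


class TestCountRate:
    @pytest.mark.parametrize(
        "c,r,expected", [(1, 1, 1.0), (1, 0.5, 1 / 64), (0.5, 0.8, 0.131072)]
    )
    def test_c_r6_scaling(self, c, r, expected):
        assert count_rate_ratio(c, r) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            count_rate_ratio(0.0, 1.0)


def test_molar_results_invariant_to_intensity_scale():
    """Multiplying the whole spectrum by a constant changes no molar
    result — the internal standard absorbs the scale."""
    comp = SpeciesComposition()
    acq = AcquisitionParams(noise_sigma=0.0)
    (_, spec), = generate_calibration_series([1.0], comp, 0.4, acq)
    q1 = amine_loading_from_spectrum(spec, 1.0)
    scaled = spec.copy()
    scaled.intensity = scaled.intensity * 137.0
    q2 = amine_loading_from_spectrum(scaled, 1.0)
    assert q2.moles_umol == pytest.approx(q1.moles_umol, rel=1e-12)
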