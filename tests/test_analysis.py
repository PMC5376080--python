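"""Unit conversion, PDD, conversion coefficients and the CHART worked example."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from straydose import analysis as an


class TestUnits:
    def test_zero(self):
        assert an.to_gray(0.0) == 0.0

    def test_mev_per_gram_to_gray(self):
        assert an.to_gray(1.0) == pytest.approx(1.602176634e-10, rel=1e-12)

    def test_attogray_display_scale(self):
        assert an.format_attogray(2.18e-16) == pytest.approx(218.0)

    def test_negative_rejected(self):
        with pytest.raises(an.AnalysisError):
            an.to_gray(-1.0)

    def test_round_sig(self):
        assert an.round_sig(51.1002, 3) == 51.1
        assert an.round_sig(0.00123456, 3) == 0.00123


class TestPDD:
    def test_simple_ratio(self):
        c = an.compute_pdd([(0.5, 50.0), (1.0, 100.0), (1.5, 80.0)])
        np.testing.assert_allclose(c.values_percent, [50, 100, 80])
        assert c.d_max_cm == 1.0

    def test_constant_doses_all_100(self):
        c = an.compute_pdd([(d, 7.0) for d in (1, 2, 3, 4)])
        np.testing.assert_allclose(c.values_percent, 100.0)

    def test_all_zero_rejected(self):
        with pytest.raises(an.AnalysisError):
            an.compute_pdd([(1, 0.0), (2, 0.0)])

    def test_single_bin_rejected(self):
        with pytest.raises(an.AnalysisError):
            an.compute_pdd([(1, 5.0)])

    def test_monotone_tail_detection(self):
        depths = np.arange(0.25, 30, 0.5)
        falling = 100 * np.exp(-0.05 * depths)
        c = an.PDDCurve(depths, falling, 0.25)
        assert c.monotone_tail()
        bumped = falling.copy()
        bumped[40] += 30
        assert not an.PDDCurve(depths, bumped, 0.25).monotone_tail()


def make_doses(values, position="P4"):
    return an.DoseResult({o: (v, 0.004) for o, v in values.items()}, position)


class TestConversion:
    def test_simple_ratio(self):
        t = an.compute_conversion_coefficients(
            make_doses({"liver": 250.0, "heart": 125.0}, "P3"), "liver")
        assert t.f("heart") == 0.5

    def test_target_f_is_exactly_one(self):
        for organs, target in ((("left_lung", "heart"), "left_lung"),
                               (("brain", "spine"), "brain")):
            t = an.compute_conversion_coefficients(
                make_doses({o: 100.0 + i for i, o in enumerate(organs)}),
                target)
            assert t.f(target) == 1.0

    def test_zero_target_dose_rejected(self):
        with pytest.raises(an.AnalysisError, match="undefined"):
            an.compute_conversion_coefficients(
                make_doses({"liver": 0.0, "heart": 1.0}), "liver")

    @given(st.floats(1e-6, 1e6))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, k):
        """F is unchanged under any uniform dose rescaling (fluence
        independence)."""
        base = {"left_lung": 243.0, "heart": 229.9, "spine": 85.5}
        t1 = an.compute_conversion_coefficients(make_doses(base), "left_lung")
        t2 = an.compute_conversion_coefficients(
            make_doses({o: k * v for o, v in base.items()}), "left_lung")
        for o in base:
            assert t1.f(o) == pytest.approx(t2.f(o), rel=1e-12)

    def test_error_propagation_quadrature(self):
        d = an.DoseResult({"left_lung": (200.0, 0.003),
                           "heart": (100.0, 0.004)}, "P4")
        t = an.compute_conversion_coefficients(d, "left_lung")
        assert t.values["heart"][1] == pytest.approx(math.hypot(0.003, 0.004))


class TestSchedule:
    def test_chart_consistency(self):
        s = an.CHART_SCHEDULE
        assert (s.total_dose_gy, s.n_fractions) == (54.0, 36)
        assert s.fractions_per_day * s.duration_days == 36
        assert s.dose_per_fraction_gy == pytest.approx(1.5)

    def test_inconsistent_schedule_rejected(self):
        with pytest.raises(an.AnalysisError, match="inconsistent"):
            an.FractionationSchedule(54.0, 36, 3, 11)

    def test_positive_values_required(self):
        with pytest.raises(an.AnalysisError):
            an.FractionationSchedule(-1.0, 36)


def chart_table():
    """Conversion table for the left-lung treatment with the published
    coefficients for heart, right lung, esophagus and spine."""
    return an.ConversionTable("P4", "left_lung", {
        "left_lung": (1.0, 0.002),
        "heart": (0.9463, 0.003),
        "right_lung": (0.6556, 0.003),
        "esophagus": (0.6093, 0.003),
        "spine": (0.3519, 0.003),
    })


class TestApplyConversion:
    def test_chart_heart_dose(self):
        out = an.apply_conversion(chart_table(), an.CHART_SCHEDULE)
        assert an.round_sig(out["heart"]["total_gy"], 3) == 51.1

    def test_chart_right_lung_dose(self):
        out = an.apply_conversion(chart_table(), an.CHART_SCHEDULE)
        assert an.round_sig(out["right_lung"]["total_gy"], 3) == 35.4

    def test_chart_spine_dose_rounds_to_19(self):
        out = an.apply_conversion(chart_table(), an.CHART_SCHEDULE)
        assert round(out["spine"]["total_gy"]) == 19

    def test_target_identity(self):
        out = an.apply_conversion(chart_table(), an.CHART_SCHEDULE)
        assert out["left_lung"]["total_gy"] == 54.0

    def test_per_fraction_column(self):
        out = an.apply_conversion(chart_table(), an.CHART_SCHEDULE)
        for organ, r in out.items():
            assert r["per_fraction_gy"] == pytest.approx(r["total_gy"] / 36)

    def test_linearity_in_prescribed_dose(self):
        t = chart_table()
        s1 = an.FractionationSchedule(10.0, 5)
        s2 = an.FractionationSchedule(30.0, 5)
        o1 = an.apply_conversion(t, s1)
        o2 = an.apply_conversion(t, s2)
        for organ in o1:
            assert o2[organ]["total_gy"] == pytest.approx(
                3 * o1[organ]["total_gy"], rel=1e-12)

    def test_dispersed_never_exceeds_prescribed_when_f_below_one(self):
        out = an.apply_conversion(chart_table(), an.CHART_SCHEDULE)
        for organ, r in out.items():
            if r["F"] <= 1.0:
                assert r["total_gy"] <= an.CHART_SCHEDULE.total_dose_gy + 1e-12

    def test_unknown_organ_warns_and_skips(self):
        with pytest.warns(UserWarning, match="absent"):
            out = an.apply_conversion(chart_table(), an.CHART_SCHEDULE,
                                      organs=["heart", "kidney"])
        assert "kidney" not in out and "heart" in out

    def test_wrong_position_rejected(self):
        with pytest.raises(an.AnalysisError):
            an.apply_conversion(chart_table(), an.CHART_SCHEDULE, position="P1")

    def test_report_rounding_conventions(self):
        df = an.dispersed_dose_report(chart_table(), an.CHART_SCHEDULE)
        heart = df[df.organ == "heart"].iloc[0]
        assert heart["dispersed_dose_gy"] == 51.1
        assert heart["F"] == 0.9463
        assert heart["percent_of_target"] == 94.63


class TestSpectrumSummary:
    def test_single_line(self):
        mean, _ = an.spectrum_summary([0.6516, 0.6716], [5.0])
        assert mean == pytest.approx(0.6616)

    def test_two_equal_bins(self):
        mean, table = an.spectrum_summary([0.5, 1.5, 2.5, 3.5], [4, 0, 4])
        assert mean == pytest.approx(2.0)
        assert table["probability"].sum() == pytest.approx(1.0)

    def test_zero_counts_rejected(self):
        with pytest.raises(an.AnalysisError):
            an.spectrum_summary([0, 1, 2], [0, 0])

    def test_sampled_spectrum_matches_analytic_mean(self):
        from straydose.scenario import BeamSource, synthetic_6mv_spectrum
        e, p = synthetic_6mv_spectrum()
        src = BeamSource("spectrum-beam", (0, 0, 100), e, p)
        rng = np.random.default_rng(33)
        n = 100_000
        draws = np.array([src.sample_energy(rng) for _ in range(n)])
        sigma = draws.std(ddof=1) / math.sqrt(n)
        assert abs(draws.mean() - src.mean_energy) < 3 * sigma


class TestCompareSources:
    def test_identical_inputs_unity(self):
        d = make_doses({"brain": 218.0, "spine": 40.9})
        df = an.compare_sources(d, d)
        np.testing.assert_allclose(df["ratio"], 1.0)

    def test_scaled_input_gives_scaled_ratio(self):
        a = make_doses({"brain": 218.0, "spine": 40.9})
        b = make_doses({"brain": 109.0, "spine": 20.45})
        np.testing.assert_allclose(an.compare_sources(a, b)["ratio"], 2.0)

    def test_disjoint_organs_rejected(self):
        with pytest.raises(an.AnalysisError):
            an.compare_sources(make_doses({"brain": 1.0}),
                               make_doses({"spine": 1.0}))
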