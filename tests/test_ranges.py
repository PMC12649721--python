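"""Normative bands, percentage summaries, deficit scoring, bootstrap."""

import numpy as np
import pytest

import devnorm as dn
from devnorm.gate import NormalityVerdict, OutlierReport, TransformSpec

from conftest import make_table


def _toy_model(kind="none", shift=0.0, intercept=0.05, slope=0.0,
               curve=None) -> dn.NormativeModel:
    curve = curve or dn.CurveModel("quadratic", 0, 0, 0, 0, 1.0)
    return dn.NormativeModel(
        curve=curve,
        residual=dn.ResidualModel(intercept, slope, n=10**9, dof=7),
        transform=TransformSpec(kind, shift),
        gate=NormalityVerdict(0.5, 0.0, 3.0, True, True),
        outliers=OutlierReport([[], [], []], np.ones(10, dtype=bool)),
        provenance={"age_range": [5.0, 18.0], "parameter": "toy"},
    )


class TestPercentageArithmetic:
    @pytest.mark.parametrize("young, old, pct", [
        (0.2680, 0.0685, -74),   # reaction-time band shrinks 74%
        (0.6874, 0.1867, -73),   # path-length-ratio band shrinks 73%
        (82.0, 87.0, 6),         # total-hits band grows 6%
        (1.0, 1.0, 0),
    ])
    def test_interval_width_change(self, young, old, pct):
        assert dn.round_half_away(dn.interval_width_change(young, old)) == pct

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            dn.interval_width_change(0.0, 1.0)

    @pytest.mark.parametrize("changing, fixed, pct", [
        (0.268, 0.2, 34),    # age-varying RT band vs fixed-width at age 5
        (0.083, 0.2, -59),   # ... and at age 18
        (0.693, 0.4, 73),    # PLR at age 5
        (0.210, 0.4, -48),   # PLR at age 18
    ])
    def test_fixed_vs_changing_width(self, changing, fixed, pct):
        assert dn.round_half_away(dn.fixed_vs_changing_width(changing, fixed)) == pct

    @pytest.mark.parametrize("x, out", [
        (58.5, 59), (-58.5, -59), (-47.5, -48), (6.1, 6), (-0.4, 0),
    ])
    def test_round_half_away(self, x, out):
        assert dn.round_half_away(x) == out


class TestMeanCurveChange:
    def test_flat_curve_zero(self):
        nm = _toy_model()
        assert dn.mean_curve_change(nm) == pytest.approx(0.0)

    def test_doubling_curve(self):
        # linear from 1 at age 5 to 2 at age 18
        curve = dn.CurveModel("quadratic", 0, 1 / 13, 0, 0, 1 - 5 / 13)
        nm = _toy_model(curve=curve)
        assert dn.mean_curve_change(nm) == pytest.approx(100.0)

    def test_exponential_truth_hand_computed(self):
        t = dn.STUDY_TRUTHS["reaction_time"]
        curve = dn.CurveModel("exponential", t.a0, t.a1, t.a2, t.a3, t.a4)
        nm = _toy_model(curve=curve)
        expected = 100.0 * (t.mean(18, 0, 0) - t.mean(5, 0, 0)) / t.mean(5, 0, 0)
        assert dn.mean_curve_change(nm) == pytest.approx(expected)
        assert dn.round_half_away(expected) == -54

    def test_zero_crossing_signalled(self):
        curve = dn.CurveModel("quadratic", 0, 1.0, 0, 0, -5.0)  # zero at age 5
        with pytest.raises(ZeroDivisionError):
            dn.mean_curve_change(_toy_model(curve=curve))


class TestIntervalCurve:
    def test_tiny_coverage_collapses_width(self):
        band = dn.interval_curve(_toy_model(), [9.0], coverage=1e-12)
        assert band["width"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_center_is_midpoint_without_transform(self):
        band = dn.interval_curve(_toy_model(), [5.0, 11.0, 18.0])
        mid = (band["lower"] + band["upper"]) / 2
        np.testing.assert_allclose(band["center"], mid)

    @pytest.mark.parametrize("kind", ["none", "log", "sqrt", "inverse"])
    def test_bounds_ordered_for_all_transforms(self, kind):
        nm = _toy_model(kind=kind, shift=0.5,
                        curve=dn.CurveModel("quadratic", 0, 0, 0, 0, 2.0))
        band = dn.interval_curve(nm, np.linspace(5, 18, 7))
        assert (band["lower"] <= band["center"] + 1e-12).all()
        assert (band["center"] <= band["upper"] + 1e-12).all()
        assert (band["width"] > 0).all()

    def test_invalid_coverage_rejected(self):
        with pytest.raises(ValueError):
            dn.interval_curve(_toy_model(), [9.0], coverage=1.2)


class TestScoreParticipant:
    def test_on_curve_is_zero(self):
        z, deficit = dn.score_participant(_toy_model(), 9.0, 0, 0, 1.0)
        assert z == pytest.approx(0.0)
        assert not deficit

    @pytest.mark.parametrize("sign", [1, -1])
    def test_z_beyond_cutoff_flags_deficit(self, sign):
        nm = _toy_model()
        s = dn.scale_factor(nm.residual, 9.0)
        z, deficit = dn.score_participant(nm, 9.0, 0, 0, 1.0 + sign * 2.4 * s)
        assert z == pytest.approx(sign * 2.4)
        assert deficit

    def test_within_cutoff_not_flagged(self):
        nm = _toy_model()
        s = dn.scale_factor(nm.residual, 9.0)
        _, deficit = dn.score_participant(nm, 9.0, 0, 0, 1.0 + 1.5 * s)
        assert not deficit

    def test_training_rows_reproduce_stored_z(self, rt_result, rt_cohort):
        rows = rt_cohort.reset_index(drop=True)
        stored = rt_result.zscores
        for i in [0, 57, 300, 575]:
            r = rows.iloc[i]
            z, _ = dn.score_participant(rt_result.model, float(r["age"]),
                                        int(r["sex"]), int(r["hand"]),
                                        float(r["value"]))
            assert z == pytest.approx(stored["z"].iloc[i], abs=1e-10)

    def test_extrapolation_warns(self):
        with pytest.warns(UserWarning, match="outside the fitted range"):
            dn.score_participant(_toy_model(), 3.0, 0, 0, 1.0)

    def test_bad_codes_rejected(self):
        with pytest.raises(ValueError):
            dn.score_participant(_toy_model(), 9.0, 2, 0, 1.0)


class TestBootstrap:
    def _cohort(self, n, seed, noise):
        skel = dn.generate_cohort(dn.Demographics(n_participants=n, seed=seed))
        truth = dn.GroundTruthSpec(family="quadratic", a0=0.01, a1=-0.4, a4=8.0,
                                   noise_intercept=noise, noise_slope=0.0,
                                   per_hand=False)
        return dn.simulate_parameter(skel, truth, "p", seed=seed + 1)

    def test_zero_noise_gives_null_width_ci(self):
        df = self._cohort(60, 60, 0.0)
        with pytest.warns(UserWarning):
            ci = dn.bootstrap_curve_ci(df, dn.FitConfig(seed=1), "quadratic",
                                       [6.0, 12.0], B=50, seed=2,
                                       includes_hand=False)
        np.testing.assert_allclose(ci["center_hi"] - ci["center_lo"], 0.0,
                                   atol=1e-8)

    def test_deterministic_under_seed(self):
        df = self._cohort(50, 61, 0.5)
        kw = dict(B=40, seed=3, includes_hand=False)
        with pytest.warns(UserWarning):
            a = dn.bootstrap_curve_ci(df, dn.FitConfig(seed=1), "quadratic",
                                      [9.0], **kw)
        with pytest.warns(UserWarning):
            b = dn.bootstrap_curve_ci(df, dn.FitConfig(seed=1), "quadratic",
                                      [9.0], **kw)
        assert a.equals(b)

    def test_ci_shrinks_with_sample_size(self):
        small = self._cohort(60, 62, 0.5)
        big = self._cohort(240, 63, 0.5)
        with pytest.warns(UserWarning):
            ci_s = dn.bootstrap_curve_ci(small, dn.FitConfig(seed=1),
                                         "quadratic", [9.0], B=60, seed=4,
                                         includes_hand=False)
        with pytest.warns(UserWarning):
            ci_b = dn.bootstrap_curve_ci(big, dn.FitConfig(seed=1),
                                         "quadratic", [9.0], B=60, seed=4,
                                         includes_hand=False)
        width_s = float((ci_s["center_hi"] - ci_s["center_lo"]).iloc[0])
        width_b = float((ci_b["center_hi"] - ci_b["center_lo"]).iloc[0])
        assert width_b < width_s
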