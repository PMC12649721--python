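"""Synthetic cohort generator: determinism, demographics, noise contract."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import devnorm as dn
from devnorm.simulate import MAD_TO_SD


class TestGenerateCohort:
    def test_study_demographics(self):
        c = dn.generate_cohort(dn.study_demographics(seed=1))
        assert len(c) == 288
        assert c["age"].between(5, 18).all()
        assert set(c["sex"].unique()) <= {0, 1}

    def test_age_moments_near_targets(self):
        c = dn.generate_cohort(dn.Demographics(n_participants=20000, seed=3))
        assert c["age"].mean() == pytest.approx(13.0, abs=0.3)
        assert c["age"].std() == pytest.approx(3.2, abs=0.3)
        # recruitment skews toward older children: left-skewed age distribution
        assert c["age"].skew() < -0.2

    def test_single_participant(self):
        c = dn.generate_cohort(dn.Demographics(n_participants=1, seed=0))
        assert len(c) == 1
        assert 5 <= c["age"].iloc[0] <= 18

    def test_deterministic_under_seed(self):
        demo = dn.Demographics(n_participants=50, seed=42)
        pd.testing.assert_frame_equal(dn.generate_cohort(demo),
                                      dn.generate_cohort(demo))

    @pytest.mark.parametrize("bad", [
        dict(age_sd=-1.0),
        dict(age_mean=25.0),
        dict(n_participants=0),
        dict(male_fraction=1.5),
        dict(age_min=18.0, age_max=5.0),
    ])
    def test_infeasible_demographics_rejected(self, bad):
        with pytest.raises(ValueError):
            dn.generate_cohort(dn.Demographics(**bad))


class TestSimulateParameter:
    def test_zero_noise_lies_on_curve(self):
        skel = dn.generate_cohort(dn.Demographics(n_participants=40, seed=5))
        truth = dn.GroundTruthSpec(family="exponential", a0=2.0, a1=-0.1,
                                   a2=0.3, a3=0.1, a4=0.5, per_hand=True)
        sim = dn.simulate_parameter(skel, truth, "p", seed=6)
        expected = truth.mean(sim["age"], sim["sex"], sim["hand"])
        np.testing.assert_allclose(sim["value"], expected, atol=1e-12)

    def test_constant_quadratic_truth(self):
        skel = dn.generate_cohort(dn.Demographics(n_participants=10, seed=5))
        truth = dn.GroundTruthSpec(family="quadratic", a4=7.0, per_hand=False)
        sim = dn.simulate_parameter(skel, truth, "p", seed=6)
        assert (sim["value"] == 7.0).all()

    def test_per_hand_emits_both_hands(self):
        skel = dn.generate_cohort(dn.Demographics(n_participants=30, seed=5))
        truth = dn.GroundTruthSpec(family="quadratic", a4=1.0, per_hand=True)
        sim = dn.simulate_parameter(skel, truth, "p", seed=6)
        assert len(sim) == 60
        assert (sim.groupby("participant_id")["hand"].agg(set) == {0, 1}).all()

    @pytest.mark.parametrize("shape", ["normal", "skewed"])
    def test_noise_contract_expected_absolute_deviation(self, shape):
        """Monte Carlo: sample mean of |value − mean curve| matches m(age)."""
        m = 0.4
        skel = dn.generate_cohort(dn.Demographics(n_participants=100_000, seed=7))
        truth = dn.GroundTruthSpec(family="quadratic", a4=5.0,
                                   noise_intercept=m, noise_slope=0.0,
                                   noise_shape=shape, skew=2.0, per_hand=False)
        sim = dn.simulate_parameter(skel, truth, "p", seed=8)
        eps = sim["value"].to_numpy() - 5.0
        # SE of the mean absolute deviation estimate
        se = np.std(np.abs(eps), ddof=1) / np.sqrt(eps.size)
        assert abs(np.abs(eps).mean() - m) < 3 * se

    def test_normal_noise_sd_is_mad_times_root_half_pi(self):
        m = 0.4
        skel = dn.generate_cohort(dn.Demographics(n_participants=100_000, seed=9))
        truth = dn.GroundTruthSpec(family="quadratic", a4=0.0,
                                   noise_intercept=m, noise_slope=0.0,
                                   per_hand=False)
        eps = dn.simulate_parameter(skel, truth, "p", seed=10)["value"].to_numpy()
        target = m * MAD_TO_SD
        se = target / np.sqrt(2 * (eps.size - 1))
        assert abs(np.std(eps, ddof=1) - target) < 3 * se

    def test_skewed_noise_has_requested_skewness(self):
        from scipy import stats
        skel = dn.generate_cohort(dn.Demographics(n_participants=200_000, seed=9))
        truth = dn.GroundTruthSpec(family="quadratic", a4=0.0,
                                   noise_intercept=1.0, noise_slope=0.0,
                                   noise_shape="skewed", skew=2.0, per_hand=False)
        eps = dn.simulate_parameter(skel, truth, "p", seed=10)["value"].to_numpy()
        assert stats.skew(eps) == pytest.approx(2.0, abs=0.15)

    def test_nonpositive_exponential_values_warn(self):
        skel = dn.generate_cohort(dn.Demographics(n_participants=200, seed=5))
        truth = dn.GroundTruthSpec(family="exponential", a0=0.01, a1=0.0, a4=0.0,
                                   noise_intercept=1.0, noise_slope=0.0,
                                   per_hand=False)
        with pytest.warns(UserWarning, match="nonpositive"):
            dn.simulate_parameter(skel, truth, "p", seed=6)


class TestDuplicateHands:
    def test_doubles_cohort(self):
        skel = dn.generate_cohort(dn.Demographics(n_participants=288, seed=1))
        out = dn.duplicate_hands(skel)
        assert len(out) == 576
        assert sorted(out["hand"].unique()) == [0, 1]

    def test_preserves_non_hand_fields(self):
        skel = dn.generate_cohort(dn.Demographics(n_participants=20, seed=1))
        out = dn.duplicate_hands(skel)
        for hand in (0, 1):
            half = (out[out["hand"] == hand]
                    .sort_values("participant_id").reset_index(drop=True))
            ref = skel.sort_values("participant_id").reset_index(drop=True)
            for col in ("participant_id", "age", "sex", "parameter"):
                assert (half[col].to_numpy() == ref[col].to_numpy()).all()

    def test_single_and_empty(self):
        skel = dn.generate_cohort(dn.Demographics(n_participants=1, seed=1))
        assert len(dn.duplicate_hands(skel)) == 2
        assert len(dn.duplicate_hands(skel.iloc[0:0])) == 0

    def test_already_duplicated_rejected(self):
        skel = dn.generate_cohort(dn.Demographics(n_participants=4, seed=1))
        doubled = dn.duplicate_hands(skel)
        with pytest.raises(ValueError, match="duplicated"):
            dn.duplicate_hands(doubled)


class TestMissBias:
    @pytest.mark.parametrize("x, w, expected", [
        ([-5, 5], [3, 3], 0.0),
        ([-2, 0, 2], [3, 1, 0], -1.5),
        ([4], [7], 4.0),
    ])
    def test_weighted_mean(self, x, w, expected):
        assert dn.miss_bias_weighted_mean(x, w) == pytest.approx(expected)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            dn.miss_bias_weighted_mean([1.0, 2.0], [0, 0])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            dn.miss_bias_weighted_mean([1.0, 2.0], [1, -1])

    @settings(derandomize=True, max_examples=50)
    @given(
        x=st.lists(st.floats(-50, 50), min_size=1, max_size=10),
        shift=st.floats(-100, 100),
        data=st.data(),
    )
    def test_translation_equivariance(self, x, shift, data):
        w = data.draw(st.lists(st.integers(0, 20), min_size=len(x),
                               max_size=len(x)).filter(lambda ws: sum(ws) > 0))
        base = dn.miss_bias_weighted_mean(x, w)
        shifted = dn.miss_bias_weighted_mean([xi + shift for xi in x], w)
        assert shifted == pytest.approx(base + shift, abs=1e-9)
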