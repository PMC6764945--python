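"""Relative/absolute quantification, risk calls, trend classification and
survival stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirarmkit import arm_stats, synthetic
from mirarmkit.arm_stats import DeRule, InputError


def ct_table(rows):
    return pd.DataFrame(rows, columns=["sample", "gene", "condition", "ct"])


class TestDdct:
    def test_equal_cts_give_unit_ratio(self):
        ct = ct_table(
            [("s1", "g", "tumor", 25.0), ("s1", "u6", "tumor", 25.0),
             ("s1", "g", "normal", 25.0), ("s1", "u6", "normal", 25.0)]
        )
        rel = arm_stats.ddct_relative_expression(ct, "g", "u6")
        assert rel["ratio"].iloc[0] == pytest.approx(1.0)
        assert rel["call"].iloc[0] == "high"  # exactly 1.0 is not low

    def test_hand_computed_example(self):
        # dCt(tumor) = 20-15 = 5, dCt(normal) = 22-15 = 7, ddCt = -2, ratio 4
        ct = ct_table(
            [("s1", "g", "tumor", 20.0), ("s1", "u6", "tumor", 15.0),
             ("s1", "g", "normal", 22.0), ("s1", "u6", "normal", 15.0)]
        )
        rel = arm_stats.ddct_relative_expression(ct, "g", "u6")
        assert rel["delta_delta_ct"].iloc[0] == pytest.approx(-2.0)
        assert rel["ratio"].iloc[0] == pytest.approx(4.0)

    def test_replicates_summarized_by_median(self):
        ct = ct_table(
            [("s1", "g", "tumor", 20.0), ("s1", "g", "tumor", 20.0),
             ("s1", "g", "tumor", 35.0),  # outlier well
             ("s1", "u6", "tumor", 15.0),
             ("s1", "g", "normal", 22.0), ("s1", "u6", "normal", 15.0)]
        )
        rel = arm_stats.ddct_relative_expression(ct, "g", "u6")
        assert rel["ratio"].iloc[0] == pytest.approx(4.0)

    def test_missing_reference_rejected(self):
        ct = ct_table([("s1", "g", "tumor", 20.0), ("s1", "g", "normal", 22.0)])
        with pytest.raises(InputError):
            arm_stats.ddct_relative_expression(ct, "g", "u6")

    @given(fold_a=st.floats(0.1, 10), fold_b=st.floats(0.1, 10))
    def test_ratio_multiplicative_in_fold_effects(self, fold_a, fold_b):
        """2^-ddCt of a combined fold equals the product of the ratios."""
        def ratio(fold):
            ct = ct_table(
                [("s", "g", "tumor", 25.0 - np.log2(fold)), ("s", "u6", "tumor", 15.0),
                 ("s", "g", "normal", 25.0), ("s", "u6", "normal", 15.0)]
            )
            return arm_stats.ddct_relative_expression(ct, "g", "u6")["ratio"].iloc[0]

        assert ratio(fold_a * fold_b) == pytest.approx(ratio(fold_a) * ratio(fold_b), rel=1e-9)


class TestRiskProfile:
    @staticmethod
    def rel(sample_ratios):
        return pd.DataFrame(
            {"sample": list(sample_ratios), "ratio": list(sample_ratios.values())}
        )

    def test_both_risk_factors(self):
        r5 = self.rel({"p1": 2.0, "p2": 1.0})
        r3 = self.rel({"p1": 0.5, "p2": 1.0})
        prof = arm_stats.call_risk_profile(r5, r3).set_index("patient_id")
        assert prof.loc["p1", "rf_count"] == 2

    def test_boundary_ratio_one_counts_no_risk_factor(self):
        r5 = self.rel({"p1": 1.0, "p2": 2.0})
        r3 = self.rel({"p1": 1.0, "p2": 0.5})
        prof = arm_stats.call_risk_profile(r5, r3).set_index("patient_id")
        assert prof.loc["p1", "rf_count"] == 0

    def test_score_is_z5_minus_z3_with_unit_weights(self):
        # construct a cohort where p1 has z5=+1, z3=-1 exactly
        r5 = self.rel({"p1": 4.0, "p2": 1.0})
        r3 = self.rel({"p1": 0.25, "p2": 1.0})
        prof = arm_stats.call_risk_profile(r5, r3).set_index("patient_id")
        assert prof.loc["p1", "risk_score"] == pytest.approx(2.0)

    def test_score_increases_in_5p_and_decreases_in_3p(self):
        """Finite-difference monotonicity of the risk score."""
        base5 = {"p1": 2.0, "p2": 1.0, "p3": 0.7}
        base3 = {"p1": 0.5, "p2": 1.0, "p3": 1.5}
        prof = arm_stats.call_risk_profile(self.rel(base5), self.rel(base3))
        up5 = arm_stats.call_risk_profile(
            self.rel({**base5, "p1": 3.0}), self.rel(base3)
        )
        down3 = arm_stats.call_risk_profile(
            self.rel(base5), self.rel({**base3, "p1": 0.4})
        )
        s0 = prof.set_index("patient_id")["risk_score"]
        assert up5.set_index("patient_id").loc["p1", "risk_score"] > s0["p1"]
        assert down3.set_index("patient_id").loc["p1", "risk_score"] > s0["p1"]

    def test_missing_arm_rejected(self):
        with pytest.raises(InputError):
            arm_stats.call_risk_profile(
                self.rel({"p1": 2.0}), self.rel({"p1": 0.5, "p2": 1.0})
            )


class TestArmTrend:
    @staticmethod
    def paired(fold5, fold3, n=50, sd=0.3, seed=0):
        rng = np.random.default_rng(seed)
        n5 = np.exp(rng.normal(0, sd, n))
        n3 = np.exp(rng.normal(0, sd, n))
        t5 = fold5 * np.exp(rng.normal(0, sd, n))
        t3 = fold3 * np.exp(rng.normal(0, sd, n))
        return t5, n5, t3, n3

    @pytest.mark.parametrize(
        "fold5,fold3,expected",
        [
            (4.0, 0.25, "opposite"),
            (0.25, 4.0, "opposite"),
            (0.25, 0.25, "same"),
            (4.0, 4.0, "same"),
            (4.0, 1.0, "single"),
            (1.0, 1.0, "none"),
        ],
    )
    def test_trend_labels(self, fold5, fold3, expected):
        res = arm_stats.classify_arm_trend(*self.paired(fold5, fold3))
        assert res["trend"] == expected

    def test_unequal_pairing_rejected(self):
        with pytest.raises(InputError):
            arm_stats.classify_arm_direction([1, 2, 3], [1, 2])

    def test_summary_counts_and_order_invariance(self):
        labels = ["same"] * 6 + ["opposite"] * 3 + ["none"] * 1
        s1 = arm_stats.arm_trend_summary(labels)
        s2 = arm_stats.arm_trend_summary(labels[::-1])
        pd.testing.assert_frame_equal(s1, s2)
        assert s1["proportion"].sum() == pytest.approx(1.0)
        assert s1.loc["same", "count"] == 6

    def test_all_same_down_gives_proportion_one(self):
        s = arm_stats.arm_trend_summary(["same"] * 10)
        assert s.loc["same", "proportion"] == 1.0

    def test_empty_summary_rejected(self):
        with pytest.raises(InputError):
            arm_stats.arm_trend_summary([])


class TestCopyNumber:
    def test_zero_mass_gives_zero_copies(self):
        assert arm_stats.copy_number_from_mass(0.0, 1000) == 0.0

    def test_printed_formula_hand_value(self):
        # 6.02e23 * 1e-6 / (1000 * 308.95 * 2)
        copies = arm_stats.copy_number_from_mass(1e-6, 1000)
        assert copies == pytest.approx(9.7427e11, rel=1e-4)

    @given(
        amount=st.floats(1e-12, 1e-3), length=st.floats(10, 1e5)
    )
    def test_doubling_length_halves_copies(self, amount, length):
        c1 = arm_stats.copy_number_from_mass(amount, length)
        c2 = arm_stats.copy_number_from_mass(amount, 2 * length)
        assert c2 == pytest.approx(c1 / 2, rel=1e-12)

    def test_single_stranded_doubles_copies(self):
        ds = arm_stats.copy_number_from_mass(1e-6, 1000, "double")
        ss = arm_stats.copy_number_from_mass(1e-6, 1000, "single")
        assert ss == pytest.approx(2 * ds, rel=1e-12)

    def test_invalid_length_rejected(self):
        with pytest.raises(InputError):
            arm_stats.copy_number_from_mass(1e-6, 0)


class TestStandardCurve:
    def test_noise_free_recovery(self):
        copies = [10.0 ** k for k in range(1, 11)]
        ct = [35.0 - 3.3219 * k for k in range(1, 11)]
        curve = arm_stats.fit_standard_curve(copies, ct)
        assert curve.slope == pytest.approx(-3.3219, abs=1e-9)
        assert curve.intercept == pytest.approx(35.0, abs=1e-9)
        assert curve.efficiency == pytest.approx(1.0, abs=1e-4)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_quantify_at_intercept_gives_one_copy(self):
        curve = arm_stats.StandardCurve(slope=-3.3219, intercept=35.0, r_squared=1.0)
        assert arm_stats.absolute_quantify(35.0, curve) == pytest.approx(1.0)

    def test_quantify_inverts_fit(self):
        curve = arm_stats.StandardCurve(slope=-3.4, intercept=36.0, r_squared=1.0)
        for copies in (1e2, 1e5, 1e8):
            ct = curve.intercept + curve.slope * np.log10(copies)
            assert arm_stats.absolute_quantify(ct, curve) == pytest.approx(copies, rel=1e-9)

    def test_requires_three_points_spanning_two_logs(self):
        with pytest.raises(InputError):
            arm_stats.fit_standard_curve([10, 100], [30, 27])
        with pytest.raises(InputError):
            arm_stats.fit_standard_curve([10, 20, 30], [30, 29, 28.5])


class TestKmLogrank:
    def test_identical_groups_give_null_statistic(self):
        df = pd.DataFrame(
            {"time": [5, 10, 15, 20] * 2, "event": [True] * 8,
             "group": ["a"] * 4 + ["b"] * 4}
        )
        _, stat, p = arm_stats.km_logrank(df)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_all_censored_group_curve_stays_at_one(self):
        df = pd.DataFrame(
            {"time": [5, 10, 15, 2, 4, 6], "event": [False] * 3 + [True] * 3,
             "group": ["flat"] * 3 + ["drop"] * 3}
        )
        curves, _, _ = arm_stats.km_logrank(df)
        assert (curves["flat"]["survival"] == 1.0).all()

    def test_km_equals_one_minus_ecdf_for_all_event_data(self):
        times = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        df = pd.DataFrame(
            {"time": np.concatenate([times, times + 100]),
             "event": True,
             "group": ["a"] * 6 + ["b"] * 6}
        )
        curves, _, _ = arm_stats.km_logrank(df)
        curve = curves["a"].set_index("time")["survival"]
        for t in times:
            assert curve.loc[t] == pytest.approx(1.0 - (times <= t).mean())

    def test_simulated_high_risk_group_has_lower_curve(self):
        cfg = synthetic.SimConfig(seed=7, hazard_beta=1.0, censor_rate=0.1)
        rng = np.random.default_rng(7)
        scores = {f"P{i}": s for i, s in enumerate(rng.normal(0, 1.4, 200))}
        surv, _ = synthetic.gen_survival(cfg, scores)
        groups = arm_stats.median_split_groups(scores)
        surv["group"] = surv["patient_id"].map(groups)
        curves, stat, p = arm_stats.km_logrank(surv)
        assert p < 0.05
        t_med = np.median(surv["time"])
        def survival_at(curve, t):
            before = curve[curve["time"] <= t]
            return before["survival"].iloc[-1] if len(before) else 1.0
        assert survival_at(curves["high"], t_med) < survival_at(curves["low"], t_med)

    def test_single_group_rejected(self):
        df = pd.DataFrame({"time": [1, 2], "event": [True, True], "group": ["a", "a"]})
        with pytest.raises(InputError):
            arm_stats.km_logrank(df)
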