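import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from syngrowth import (
    DegenerateInputError,
    InsufficientDataError,
    ValidationError,
    body_weight_loss,
    classify_combination,
    complete_responders,
    gri_test,
    growth_rate_inhibition,
    synergy_score,
    synergy_score_value,
    tc_ratio,
    welch_satterthwaite_df,
)
from syngrowth.efficacy import SynergyResult
from syngrowth.growth import GroupGrowthSummary

from .conftest import make_table


def summary(group, mean, se=0.01, n=10):
    """Arm summary with prescribed mean/SE, dispersing rates to match.

    The rates vector is n values with the requested mean and sample
    SD = se * sqrt(n), built from a fixed +/- pattern.
    """
    sd = se * math.sqrt(n)
    half = n // 2
    devs = np.array([1.0] * half + [-1.0] * half)
    if n % 2:
        devs = np.append(devs, 0.0)
    devs = devs / devs.std(ddof=1) if devs.std(ddof=1) else devs
    rates = mean + sd * devs
    s = GroupGrowthSummary.from_rates(group, rates)
    assert s.mean_rate == pytest.approx(mean, abs=1e-12)
    assert s.se == pytest.approx(se, abs=1e-12)
    return s


class TestGri:
    @pytest.mark.parametrize(
        "mu_t,mu_c,mu_v,expected",
        [(0.15, 0.30, 0.30, 50.0), (0.30, 0.30, 0.30, 0.0), (0.0, 0.30, 0.30, 100.0)],
    )
    def test_formula(self, mu_t, mu_c, mu_v, expected):
        res = growth_rate_inhibition(
            summary("t", mu_t), summary("c", mu_c), summary("v", mu_v)
        )
        assert res.gri_percent == pytest.approx(expected, abs=1e-9)

    def test_vehicle_defaults_to_control(self):
        res = growth_rate_inhibition(summary("t", 0.15), summary("c", 0.30))
        assert res.gri_percent == pytest.approx(50.0, abs=1e-9)
        assert res.vehicle == "c"

    def test_zero_vehicle_rate_degenerate(self):
        with pytest.raises(DegenerateInputError):
            growth_rate_inhibition(
                summary("t", 0.1), summary("c", 0.2), summary("v", 0.0)
            )

    def test_antisymmetric_in_treatment_control(self):
        t, c, v = summary("t", 0.12), summary("c", 0.27), summary("v", 0.30)
        assert growth_rate_inhibition(t, c, v).gri_percent == pytest.approx(
            -growth_rate_inhibition(c, t, v).gri_percent
        )

    @given(st.floats(0.2, 5.0))
    def test_time_unit_invariance(self, c):
        """GRI is a rate ratio: rescaling all rates jointly leaves it fixed."""
        base = growth_rate_inhibition(
            summary("t", 0.15), summary("c", 0.30), summary("v", 0.25)
        ).gri_percent
        scaled = growth_rate_inhibition(
            summary("t", 0.15 * c, se=0.01 * c),
            summary("c", 0.30 * c, se=0.01 * c),
            summary("v", 0.25 * c, se=0.01 * c),
        ).gri_percent
        assert scaled == pytest.approx(base, rel=1e-9)


class TestGriTest:
    def test_identical_rates_p_one(self):
        rates = [0.1, 0.2, 0.3]
        g1 = GroupGrowthSummary.from_rates("a", rates)
        g2 = GroupGrowthSummary.from_rates("b", rates)
        p, _ = gri_test(g1, g2)
        assert p == pytest.approx(1.0)

    def test_matches_hand_welch_formula(self):
        g1 = GroupGrowthSummary.from_rates("a", [0.30, 0.31, 0.29])
        g2 = GroupGrowthSummary.from_rates("b", [0.10, 0.11, 0.09])
        p, df = gri_test(g1, g2)
        # frozen from the closed-form Welch t and Welch-Satterthwaite df
        assert df == pytest.approx(4.0, abs=1e-9)
        assert p == pytest.approx(1.6483088987181252e-05, rel=1e-9)

    def test_single_animal_group_rejected(self):
        g1 = GroupGrowthSummary("a", 0.2, 0.0, 1, 0, (0.2,))
        g2 = GroupGrowthSummary.from_rates("b", [0.1, 0.2])
        with pytest.raises(InsufficientDataError):
            gri_test(g1, g2)


class TestSynergyScore:
    def test_additive_null_is_zero_for_any_ses(self):
        for se in (0.005, 0.02, 0.04):
            res = synergy_score(
                summary("AB", 0.12, se=se),
                summary("A", 0.20, se=se),
                summary("B", 0.22, se=se),
                summary("control", 0.30, se=se),
            )
            assert res.score_percent == pytest.approx(0.0, abs=1e-9)

    def test_printed_formula_value(self):
        res = synergy_score(
            summary("AB", 0.05),
            summary("A", 0.2),
            summary("B", 0.2),
            summary("control", 0.3),
        )
        assert res.score_percent == pytest.approx(-100 / 6, abs=1e-9)

    def test_welch_satterthwaite_df_hand_evaluated(self):
        ses = [0.02, 0.015, 0.015, 0.01]
        res = synergy_score(
            summary("AB", 0.12, se=ses[0]),
            summary("A", 0.20, se=ses[1]),
            summary("B", 0.22, se=ses[2]),
            summary("control", 0.30, se=ses[3]),
        )
        # frozen from (sum se^2)^2 / sum(se^4 / 9)
        assert res.df == pytest.approx(29.9447004608295, rel=1e-12)
        # SE: root-sum-of-squares scaled by 100/|mu_V|
        assert res.se == pytest.approx(
            100 * math.sqrt(sum(s**2 for s in ses)) / 0.30, rel=1e-12
        )
        assert res.t_stat == pytest.approx(res.score_percent / res.se)
        assert res.p_value == pytest.approx(
            2 * stats.t.sf(abs(res.t_stat), res.df), rel=1e-12
        )

    def test_df_reduces_to_two_sample_welch_when_two_ses_vanish(self):
        df4 = welch_satterthwaite_df([0.02, 0.0, 0.0, 0.01], [10, 10, 10, 10])
        v1, v2 = 0.02**2, 0.01**2
        df2 = (v1 + v2) ** 2 / (v1**2 / 9 + v2**2 / 9)
        assert df4 == pytest.approx(df2, rel=1e-12)

    @given(
        ses=st.lists(st.floats(1e-4, 0.05), min_size=4, max_size=4),
        ns=st.lists(st.integers(2, 30), min_size=4, max_size=4),
    )
    def test_df_bounds(self, ses, ns):
        """min(n_i - 1) <= df <= sum(n_i - 1)."""
        df = welch_satterthwaite_df(ses, ns)
        assert min(n - 1 for n in ns) - 1e-9 <= df <= sum(n - 1 for n in ns) + 1e-9

    @given(st.floats(0.0, 0.4), st.floats(0.01, 0.1))
    def test_strictly_increasing_in_combination_rate(self, mu_ab, delta):
        """Slope of the score in mu_AB is 100/mu_V."""
        args = dict(mu_a=0.2, mu_b=0.22, mu_control=0.3, mu_v=0.25)
        lo = synergy_score_value(mu_ab, **args)
        hi = synergy_score_value(mu_ab + delta, **args)
        assert hi > lo
        assert (hi - lo) / delta == pytest.approx(100 / 0.25, rel=1e-6)

    def test_zero_vehicle_degenerate(self):
        with pytest.raises(DegenerateInputError):
            synergy_score(
                summary("AB", 0.1),
                summary("A", 0.2),
                summary("B", 0.2),
                summary("control", 0.3),
                summary("vehicle", 0.0),
            )

    def test_all_zero_ses_degenerate(self):
        # binary-exact rates so each arm's sample SD is exactly 0
        def constant(group, rate):
            return GroupGrowthSummary.from_rates(group, [rate] * 4)

        with pytest.raises(DegenerateInputError):
            synergy_score(
                constant("AB", 0.125),
                constant("A", 0.25),
                constant("B", 0.25),
                constant("control", 0.5),
            )

    def test_vehicle_error_term_widens_se(self):
        groups = dict(
            ab=summary("AB", 0.05),
            a=summary("A", 0.2),
            b=summary("B", 0.2),
            control=summary("control", 0.3),
        )
        fixed = synergy_score(**groups)
        delta = synergy_score(**groups, vehicle_error_term=True)
        assert delta.se > fixed.se


class TestClassifyCombination:
    @pytest.mark.parametrize(
        "score,p,mu_ab,mu_a,mu_b,expected",
        [
            (-20.0, 0.01, 0.05, 0.2, 0.2, "synergistic"),
            (15.0, 0.40, 0.10, 0.2, 0.25, "additive"),
            (-20.0, 0.30, 0.05, 0.2, 0.2, "additive"),
            (15.0, 0.01, 0.10, 0.20, 0.25, "sub-additive"),
            (15.0, 0.01, 0.22, 0.20, 0.25, "antagonistic"),
        ],
    )
    def test_rules(self, score, p, mu_ab, mu_a, mu_b, expected):
        syn = SynergyResult(score, 5.0, 20.0, score / 5.0, p, "additive", {})
        label = classify_combination(
            syn, summary("AB", mu_ab), summary("A", mu_a), summary("B", mu_b)
        )
        assert label == expected

    @given(
        score=st.floats(-50, 50),
        p=st.floats(0, 1),
        mu_ab=st.floats(0.01, 0.4),
        mu_a=st.floats(0.01, 0.4),
        mu_b=st.floats(0.01, 0.4),
    )
    def test_exhaustive_and_deterministic(self, score, p, mu_ab, mu_a, mu_b):
        syn = SynergyResult(score, 5.0, 20.0, score / 5.0, p, "additive", {})
        args = (syn, summary("AB", mu_ab), summary("A", mu_a), summary("B", mu_b))
        label = classify_combination(*args)
        assert label in {"synergistic", "additive", "sub-additive", "antagonistic"}
        assert classify_combination(*args) == label

    def test_bad_alpha_rejected(self):
        syn = SynergyResult(1.0, 5.0, 20.0, 0.2, 0.5, "additive", {})
        with pytest.raises(ValidationError):
            classify_combination(
                syn, summary("AB", 0.1), summary("A", 0.2), summary("B", 0.2), alpha=1.5
            )


class TestTcRatio:
    def _arms(self, t_vols, c_vols, day=5):
        t = make_table([(f"t{i}", "t", day, v) for i, v in enumerate(t_vols)])
        c = make_table([(f"c{i}", "c", day, v) for i, v in enumerate(c_vols)])
        return t.data, c.data

    def test_equal_means_100(self):
        t, c = self._arms([100, 200], [150, 150])
        assert tc_ratio(t, c, 5) == pytest.approx(100.0)

    def test_half_is_50(self):
        t, c = self._arms([50, 100], [100, 200])
        assert tc_ratio(t, c, 5) == pytest.approx(50.0)

    def test_missing_day_rejected(self):
        t, c = self._arms([50], [100])
        with pytest.raises(ValidationError):
            tc_ratio(t, c, 7)

    def test_zero_control_mean_degenerate(self):
        t, c = self._arms([50], [0])
        with pytest.raises(DegenerateInputError):
            tc_ratio(t, c, 5)


class TestBodyWeightLoss:
    def test_constant_weights_zero_loss(self):
        table = make_table(
            [("a", "g", d, 30.0, 20.0) for d in (0, 3, 7)]
            + [("b", "g", d, 30.0, 22.0) for d in (0, 3, 7)]
        )
        bwl = body_weight_loss(table)["g"]
        assert bwl.max_mean_bwl_percent == 0.0
        assert all(v == 0.0 for v in bwl.mean_bwl_percent_by_day.values())

    def test_hand_computed_arm_mean(self):
        table = make_table(
            [("a", "g", 0, 30.0, 20.0), ("a", "g", 3, 35.0, 19.0),
             ("b", "g", 0, 30.0, 20.0), ("b", "g", 3, 35.0, 20.0)]
        )
        bwl = body_weight_loss(table)["g"]
        # animal a: -5%, animal b: 0% -> arm mean -2.5% on day 3
        assert bwl.mean_bwl_percent_by_day[3] == pytest.approx(-2.5)
        assert bwl.max_mean_bwl_percent == pytest.approx(2.5)
        assert bwl.max_day == 3

    def test_day0_mean_change_is_zero(self):
        table = make_table(
            [("a", "g", 0, 30.0, 18.0), ("a", "g", 3, 35.0, 17.0)]
        )
        assert body_weight_loss(table)["g"].mean_bwl_percent_by_day[0] == 0.0

    def test_missing_day0_weight_names_animal(self):
        table = make_table(
            [("a", "g", 0, 30.0, 20.0), ("a", "g", 3, 35.0, 19.0),
             ("b", "g", 0, 30.0), ("b", "g", 3, 35.0, 20.0)]
        )
        with pytest.raises(ValidationError, match="b"):
            body_weight_loss(table)


class TestCompleteResponders:
    def test_no_zero_volumes_no_crs(self):
        table = make_table(
            [("a", "g", 0, 30.0), ("a", "g", 10, 400.0),
             ("b", "g", 0, 30.0), ("b", "g", 10, 2.0)]
        )
        assert complete_responders(table)["g"].cr_count == 0

    def test_sustained_zero_is_cr(self):
        table = make_table(
            [("a", "g", 0, 30.0), ("a", "g", 30, 0.0), ("a", "g", 40, 0.0),
             ("b", "g", 0, 30.0), ("b", "g", 30, 100.0), ("b", "g", 40, 150.0)]
        )
        res = complete_responders(table)["g"]
        assert res.cr_count == 1 and res.cr_animals == ("a",)
        assert res.n == 2

    def test_regrowth_not_cr_under_default_policy(self):
        rows = [("a", "g", 0, 30.0), ("a", "g", 30, 0.0), ("a", "g", 40, 150.0),
                ("a", "g", 46, 0.0)]
        table = make_table(rows)
        assert complete_responders(table)["g"].cr_count == 0
        # the laxer policy only inspects the final assessment
        assert complete_responders(table, policy="final-day-zero")["g"].cr_count == 1

    def test_unknown_policy_rejected(self):
        table = make_table([("a", "g", 0, 30.0), ("a", "g", 2, 0.0)])
        with pytest.raises(ValidationError):
            complete_responders(table, policy="bogus")
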