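"""Group classification, ANCOVA/Tukey, Hedges g, and the outlier sensitivity rerun."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arcwalk.cohort_stats import (
    ParticipantRecord,
    ancova_compare,
    categorize_cognition,
    categorize_physical,
    hedges_g,
    iqr_fences,
    outlier_sensitivity,
)
from arcwalk.reference import CARE_LEVEL_N, CARE_LEVEL_SUMMARY


class TestCognitionCutoffs:
    @pytest.mark.parametrize(
        "moca,expected",
        [
            (30, "intact"), (26, "intact"),
            (25, "mild"), (18, "mild"),
            (17, "moderate"), (10, "moderate"),
            (9, "severe"), (0, "severe"),
            (None, "untested"), (float("nan"), "untested"),
        ],
    )
    def test_mapping(self, moca, expected):
        assert categorize_cognition(moca) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize_cognition(31)


class TestPhysicalCutoffs:
    @pytest.mark.parametrize(
        "sppb,expected",
        [
            (12, "high_moderate"), (7, "high_moderate"),
            (6, "low_very_low"), (0, "low_very_low"),
            (None, "untested"),
        ],
    )
    def test_mapping(self, sppb, expected):
        assert categorize_physical(sppb) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize_physical(13)


class TestParticipantRecord:
    def test_derived_labels(self):
        p = ParticipantRecord("p1", 84, "female", "rest_home", moca=12, sppb=5)
        assert p.cognition == "moderate" and p.physical == "low_very_low"

    def test_validation(self):
        with pytest.raises(ValueError):
            ParticipantRecord("p2", 84, "female", "rest_home", moca=35)


class TestHedgesG:
    def test_equal_means_zero(self):
        assert hedges_g(5.0, 1.0, 20, 5.0, 2.0, 30) == 0.0

    def test_small_sample_correction_value(self):
        # n1 = n2 = 2 -> df = 2 -> J = 1 - 3/7
        g = hedges_g(1.0, 1.0, 2, 0.0, 1.0, 2, signed=True)
        assert g == pytest.approx((1 - 3 / 7) * 1.0)

    def test_published_alpha_effect_sizes_recovered(self):
        m_h, s_h = CARE_LEVEL_SUMMARY["hospital"]["alpha"]
        m_r, s_r = CARE_LEVEL_SUMMARY["rest_home"]["alpha"]
        m_d, s_d = CARE_LEVEL_SUMMARY["dementia"]["alpha"]
        g_hd = hedges_g(m_h, s_h, CARE_LEVEL_N["hospital"], m_d, s_d, CARE_LEVEL_N["dementia"])
        g_rd = hedges_g(m_r, s_r, CARE_LEVEL_N["rest_home"], m_d, s_d, CARE_LEVEL_N["dementia"])
        assert round(g_hd, 1) == 0.9
        assert round(g_rd, 1) == 0.8

    @given(
        st.floats(-50, 50), st.floats(0.1, 20), st.integers(2, 500),
        st.floats(-50, 50), st.floats(0.1, 20), st.integers(2, 500),
    )
    @settings(max_examples=1000, deadline=None)
    def test_agrees_with_direct_formula(self, m1, s1, n1, m2, s2, n2):
        df = n1 + n2 - 2
        sp = math.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df)
        expected = abs((1 - 3 / (4 * df - 1)) * (m1 - m2) / sp)
        assert hedges_g(m1, s1, n1, m2, s2, n2) == pytest.approx(expected, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            hedges_g(1, 0.0, 10, 2, 1.0, 10)
        with pytest.raises(ValueError):
            hedges_g(1, 1.0, 1, 2, 1.0, 10)


def cohort(rng, k=3, n=40, effect=0.0, age_slope=0.0):
    groups = np.repeat([f"g{i}" for i in range(k)], n)
    age = rng.normal(84, 7, k * n)
    sex = rng.choice(["female", "male"], k * n)
    y = rng.normal(0, 1, k * n) + age_slope * (age - 84)
    for i in range(k):
        y[groups == f"g{i}"] += i * effect
    return pd.DataFrame({"group": groups, "age": age, "sex": sex, "y": y})


class TestAncova:
    def test_group_effect_detected(self, rng):
        df = cohort(rng, effect=1.0)
        res = ancova_compare(df, "y", "group")
        assert res.p_value < 1e-6
        assert len(res.pairwise) == 3  # k(k-1)/2

    def test_reduces_to_anova_without_covariates(self, rng):
        from scipy.stats import f_oneway

        df = cohort(rng, effect=0.3)
        res = ancova_compare(df, "y", "group", covariates=())
        ref = f_oneway(*[df.y[df.group == g] for g in sorted(df.group.unique())])
        assert res.f_statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_adjusted_means_equal_raw_when_covariates_balanced(self, rng):
        # identical covariate values in every group: adjustment changes nothing
        n = 30
        age = rng.normal(84, 7, n)
        sex = rng.choice(["female", "male"], n)
        df = pd.DataFrame(
            {
                "group": np.repeat(["a", "b", "c"], n),
                "age": np.tile(age, 3),
                "sex": np.tile(sex, 3),
                "y": rng.normal(0, 1, 3 * n) + np.repeat([0.0, 1.0, 2.0], n),
            }
        )
        res = ancova_compare(df, "y", "group")
        for g in ("a", "b", "c"):
            assert res.adjusted_means[g] == pytest.approx(
                float(df.y[df.group == g].mean()), abs=1e-8
            )

    def test_covariate_adjustment_removes_age_confound(self, rng):
        # outcome depends on age only; one group is systematically older, so
        # the raw comparison is confounded and the adjusted one is not
        n = 50
        groups = np.repeat(["g0", "g1", "g2"], n)
        age = rng.normal(84, 7, 3 * n)
        age[groups == "g2"] += 10
        y = 0.2 * (age - 84) + rng.normal(0, 1, 3 * n)
        df = pd.DataFrame({"group": groups, "age": age, "y": y})
        adj = ancova_compare(df, "y", "group", covariates=("age",))
        raw = ancova_compare(df, "y", "group", covariates=())
        assert raw.p_value < 0.01
        assert adj.p_value > raw.p_value

    def test_missing_covariates_dropped_and_counted(self, rng):
        df = cohort(rng)
        df.loc[:4, "age"] = np.nan
        res = ancova_compare(df, "y", "group")
        assert res.dropped_missing_covariates == 5

    def test_small_group_rejected(self, rng):
        df = cohort(rng, n=10)
        df = df[~((df.group == "g0") & (df.index % 10 < 8))]
        with pytest.raises(ValueError, match="too small"):
            ancova_compare(df, "y", "group")

    def test_singular_design_named(self, rng):
        df = cohort(rng)
        df["age2"] = df.age  # collinear duplicate
        with pytest.raises(ValueError, match="singular"):
            ancova_compare(df, "y", "group", covariates=("age", "age2"))

    def test_tukey_familywise_error_controlled(self, rng):
        fwe = 0
        reps = 400
        for _ in range(reps):
            df = cohort(rng, n=20)
            res = ancova_compare(df, "y", "group", diagnostics=False)
            if any(pw.tukey_p < 0.05 for pw in res.pairwise):
                fwe += 1
        assert fwe / reps <= 0.06  # alpha + 1%


class TestOutlierSensitivity:
    def test_no_outliers_identical_to_primary(self, rng):
        df = cohort(rng)
        primary = ancova_compare(df, "y", "group")
        sens = outlier_sensitivity(df, "y", "group")
        assert sens.outliers_removed == 0
        assert sens.f_statistic == pytest.approx(primary.f_statistic)

    def test_single_extreme_point_removed(self, rng):
        df = cohort(rng)
        df.loc[0, "y"] = 50.0
        sens = outlier_sensitivity(df, "y", "group")
        assert sens.outliers_removed == 1

    def test_fences_idempotent(self, rng):
        x = rng.normal(0, 1, 500)
        x[:5] += 20
        lo, hi = iqr_fences(x)
        kept = x[(x >= lo) & (x <= hi)]
        lo2, hi2 = iqr_fences(kept)
        kept2 = kept[(kept >= lo2) & (kept <= hi2)]
        # reapplying to already-cleaned data removes (almost) nothing
        assert kept2.size >= kept.size - 2

    def test_significance_can_flip_with_planted_outliers(self, rng):
        # heavy-tailed outcome: a significant difference driven by outliers
        # disappears after fence removal
        n = 60
        base = rng.normal(0.8, 0.08, 2 * n)
        y = base.copy()
        y[:6] = 3.0  # extreme values concentrated in one group
        df = pd.DataFrame(
            {
                "group": np.repeat(["a", "b"], n),
                "age": rng.normal(84, 7, 2 * n),
                "sex": rng.choice(["female", "male"], 2 * n),
                "y": y,
            }
        )
        primary = ancova_compare(df, "y", "group")
        sens = outlier_sensitivity(df, "y", "group")
        assert primary.p_value < 0.05
        assert sens.outliers_removed >= 5
        assert sens.p_value > primary.p_value
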