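import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radrobust.robustness import (
    Stratum,
    assign_levels,
    class_summary,
    default_strata,
    normality_gate,
    overall_score,
    pairwise_score,
    score_features,
    score_from_pvalue,
)
from radrobust.synthdata import simulate_feature_values

from _oracles import mwu_pvalue_enum


class TestNormalityGate:
    def test_normal_groups_parametric(self):
        rng = np.random.default_rng(42)
        groups = [rng.normal(size=50) for _ in range(3)]
        assert normality_gate(groups) == "parametric"

    def test_exponential_group_nonparametric(self):
        rng = np.random.default_rng(7)
        assert normality_gate([rng.exponential(size=100)]) == "nonparametric"

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            normality_gate([np.array([1.0, 2.0])])

    def test_constant_group_nonparametric(self):
        assert normality_gate([np.full(10, 3.0)]) == "nonparametric"


class TestScores:
    def test_score_is_pvalue(self):
        # the worked examples: p = 0.02 → score 0.02; p = 0.80 → score 0.80
        assert score_from_pvalue(0.02) == 0.02
        assert score_from_pvalue(0.80) == 0.80

    def test_overall_kruskal_hand_computed(self):
        # ranks give H = (12/90)·54 = 7.2 → chi-square df=2 tail
        score = overall_score([1, 2, 3], [4, 5, 6], [7, 8, 9], gate="nonparametric")
        assert score == pytest.approx(stats.chi2.sf(7.2, 2))
        assert score == pytest.approx(0.0273, abs=5e-4)

    def test_identical_groups_score_one(self):
        g = [1.0, 2.0, 3.0]
        assert overall_score(g, g, g) == 1.0
        assert pairwise_score(g, g) == 1.0

    def test_pairwise_exact_mwu(self):
        # U = 0; two-sided p = 2/C(6,3) = 0.1
        assert pairwise_score([1, 2, 3], [4, 5, 6], gate="nonparametric") == pytest.approx(0.1)

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_exact_mwu_matches_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(10):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert pairwise_score(x, y, gate="nonparametric") == pytest.approx(
                mwu_pvalue_enum(x, y)
            )

    def test_scores_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = [rng.normal(size=12) for _ in range(3)]
            assert 0.0 <= overall_score(*g) <= 1.0
            assert 0.0 <= pairwise_score(g[0], g[1]) <= 1.0

    def test_small_groups_raise(self):
        with pytest.raises(ValueError):
            pairwise_score([1.0, 2.0], [3.0, 4.0, 5.0])


class TestScoreFeatures:
    def test_report_shape_and_range(self):
        table = simulate_feature_values(60, 0.0, 0.0, 1.0, seed=3)
        rep = score_features(table)
        assert list(rep["feature"]) == ["SIM.value"]
        assert rep.loc[0, "n_original"] == 60
        for col in ("overall_score", "over_score", "under_score"):
            assert 0.0 <= rep.loc[0, col] <= 1.0

    def test_directional_shift(self):
        hits_over, miss_under = 0, 0
        for seed in range(20):
            table = simulate_feature_values(100, 5.0, 0.0, 1.0, seed=seed)
            rep = score_features(table)
            hits_over += rep.loc[0, "over_score"] < 0.05
            miss_under += rep.loc[0, "under_score"] > 0.05
        assert hits_over == 20
        assert miss_under >= 19

    def test_monotone_power(self):
        # rejection rate of the overall test is non-decreasing in the shift
        rates = []
        for shift in (0.0, 1.0, 3.0):
            rejections = 0
            for seed in range(150):
                table = simulate_feature_values(20, shift, 0.0, 1.0, seed=seed)
                rejections += score_features(table).loc[0, "overall_score"] < 0.05
            rates.append(rejections / 150)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > 0.9

    def test_case_id_relabeling_invariant(self):
        table = simulate_feature_values(50, 2.0, -1.0, 1.0, seed=8)
        relabeled = table.copy()
        relabeled["case_id"] = "x_" + relabeled["case_id"]
        rep_a = score_features(table).drop(columns="stratum")
        rep_b = score_features(relabeled).drop(columns="stratum")
        pd.testing.assert_frame_equal(rep_a, rep_b)

    def test_stratum_filtering_and_too_small(self):
        table = simulate_feature_values(30, 0.0, 0.0, 1.0, seed=1)
        # all simulated rows are mass/benign/CC
        with pytest.raises(ValueError):
            score_features(table, Stratum("calcification", "all", "all"))
        rep = score_features(table, Stratum("mass", "benign", "CC"))
        assert len(rep) == 1

    def test_degenerate_cases_excluded(self):
        table = simulate_feature_values(30, 0.0, 0.0, 1.0, seed=5)
        broken = table[
            ~((table["case_id"] == "sim0000") & (table["segmentation_class"] == "under"))
        ]
        rep = score_features(broken)
        assert rep.loc[0, "n_original"] == 29


class TestLevelsAndSummary:
    def _report(self, scores):
        return pd.DataFrame(
            {
                "stratum": "mass/benign/all",
                "family": "FO",
                "feature": [f"FO.f{i}" for i in range(len(scores))],
                "test_used": "ANOVA+t-test",
                "overall_score": scores,
                "over_score": scores,
                "under_score": scores,
                "n_original": 10,
                "n_over": 10,
                "n_under": 10,
            }
        )

    def test_median_split(self):
        rep = assign_levels(self._report([0.9, 0.8, 0.1, 0.05]))
        assert list(rep["level"]) == ["high", "high", "low", "low"]

    def test_all_equal_all_high(self):
        rep = assign_levels(self._report([0.5, 0.5, 0.5]))
        assert set(rep["level"]) == {"high"}

    def test_single_feature_raises(self):
        with pytest.raises(ValueError):
            assign_levels(self._report([0.5]))

    def test_summary_median(self):
        summary = class_summary(self._report([0.1, 0.2, 0.3]))
        row = summary[summary["score_type"] == "overall_score"].iloc[0]
        assert row["median"] == pytest.approx(0.2)
        assert row["n_features"] == 3

    def test_summary_row_order_invariant(self):
        rep = self._report([0.3, 0.1, 0.9, 0.4])
        a = class_summary(rep)
        b = class_summary(rep.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_frame_equal(a, b)

    def test_empty_report_raises(self):
        with pytest.raises(ValueError):
            class_summary(pd.DataFrame())


class TestStratum:
    def test_default_strata_count(self):
        assert len(default_strata()) == 12

    def test_bad_filter_raises(self):
        with pytest.raises(ValueError):
            Stratum(abnormality="nodule")
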