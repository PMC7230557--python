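import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from metsev import (apply_exclusions, build_tables, describe_by_tertile,
                    normality_and_variance_checks)
from metsev import stats as pstats


def make_tertiles(*groups):
    vals, labs = [], []
    for lab, g in zip(("T1", "T2", "T3"), groups):
        vals.extend(g)
        labs.extend([lab] * len(g))
    return pd.Series(vals, dtype=float), pd.Series(labs)


class TestExclusionCascade:
    def test_flow_conservation_and_counts(self):
        cohort = pd.DataFrame({"id": range(100)})
        stages = [
            ("a", pd.Series([True] * 10 + [False] * 90)),
            ("b", pd.Series([False] * 50 + [True] * 20 + [False] * 30)),
        ]
        analysed, flow = apply_exclusions(cohort, stages)
        assert flow.stage_counts == {"a": 10, "b": 20}
        assert flow.final_n == 70 == len(analysed)
        assert flow.initial_n == sum(flow.stage_counts.values()) + flow.final_n

    def test_first_failure_rule(self):
        cohort = pd.DataFrame({"id": [0, 1, 2]})
        # subject 0 fails stages 1 and 3: must be counted only at stage 1
        stages = [
            ("one", pd.Series([True, False, False])),
            ("two", pd.Series([False, False, False])),
            ("three", pd.Series([True, True, False])),
        ]
        _, flow = apply_exclusions(cohort, stages)
        assert flow.stage_counts == {"one": 1, "two": 0, "three": 1}
        assert flow.final_n == 1

    def test_no_predicate_fires(self):
        cohort = pd.DataFrame({"id": range(5)})
        _, flow = apply_exclusions(cohort, [("a", pd.Series([False] * 5))])
        assert flow.stage_counts == {"a": 0} and flow.final_n == 5

    def test_empty_cohort(self):
        cohort = pd.DataFrame({"id": []})
        analysed, flow = apply_exclusions(cohort, [])
        assert len(analysed) == 0 and flow.final_n == 0


class TestDescriptives:
    def test_hand_computation(self):
        vals, tert = make_tertiles([1, 2, 3, 4, 5], [1, 1], [2, 2])
        d = describe_by_tertile(vals, tert)
        assert d.loc["T1", "mean"] == pytest.approx(3.0)
        assert d.loc["T1", "sd"] == pytest.approx(np.std([1, 2, 3, 4, 5], ddof=1))
        assert d.loc["T1", "median"] == 3.0
        assert d.loc["T1", "iqr"] == pytest.approx(2.0)

    def test_constant_group(self):
        vals, tert = make_tertiles([5, 5, 5], [5, 5], [5])
        d = describe_by_tertile(vals, tert)
        assert d.loc["T1", "sd"] == 0.0 and d.loc["T1", "iqr"] == 0.0

    def test_categorical_percentages(self):
        vals = pd.Series(["A", "A", "B"])
        tert = pd.Series(["T1", "T1", "T1"])
        d = describe_by_tertile(vals, tert)
        assert d.loc["A", ("pct", "T1")] == pytest.approx(66.7)
        assert d.loc["B", ("pct", "T1")] == pytest.approx(33.3)


class TestChiSquare:
    def test_hand_2x2(self):
        v = pd.Series(["x"] * 10 + ["y"] * 20 + ["x"] * 20 + ["y"] * 10)
        g = pd.Series(["T1"] * 30 + ["T2"] * 30)
        p = pstats.test_categorical(v, g)
        chi2, p_ref, _, _ = sps.chi2_contingency(
            np.array([[10, 20], [20, 10]]), correction=False)
        assert chi2 == pytest.approx(20 / 3)  # 6.67
        assert p == pytest.approx(p_ref) == pytest.approx(0.0098, abs=5e-4)

    def test_identical_distributions_large_statistic_small(self):
        v = pd.Series(["x", "y"] * 300)
        g = pd.Series((["T1"] * 2 + ["T2"] * 2 + ["T3"] * 2) * 100)
        assert pstats.test_categorical(v, g) == pytest.approx(1.0)

    def test_label_permutation_invariant(self):
        rng = np.random.default_rng(0)
        v = pd.Series(rng.choice(["x", "y", "z"], 300))
        g = pd.Series(rng.choice(["T1", "T2", "T3"], 300))
        mapping = {"T1": "T3", "T2": "T1", "T3": "T2"}
        assert pstats.test_categorical(v, g) == pytest.approx(
            pstats.test_categorical(v, g.map(mapping)))


class TestAnovaAncova:
    def test_hand_anova(self):
        vals, tert = make_tertiles([1, 2, 3], [2, 3, 4], [3, 4, 5])
        res = pstats.test_quantitative(vals, tert)
        f_ref = sps.f_oneway([1, 2, 3], [2, 3, 4], [3, 4, 5])
        assert res["p"] == pytest.approx(f_ref.pvalue, rel=1e-9)
        # hand computation: MSB = 3, MSW = 1 -> F = 3, p = sf(3; 2, 6)
        assert f_ref.statistic == pytest.approx(3.0)
        assert res["p"] == pytest.approx(0.125, abs=5e-4)

    def test_two_groups_equals_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
        vals = pd.Series(np.concatenate([a, b]))
        tert = pd.Series(["T1"] * 20 + ["T3"] * 25)
        res = pstats.test_quantitative(vals, tert)
        t = sps.ttest_ind(a, b)
        assert res["p"] == pytest.approx(t.pvalue, rel=1e-9)

    def test_empty_covariates_reproduce_anova_exactly(self, scored):
        res_plain = pstats.test_quantitative(scored["bdi"], scored["tertile"])
        groups = [g.dropna() for _, g in scored.groupby("tertile", observed=True)["bdi"]]
        assert res_plain["p"] == pytest.approx(sps.f_oneway(*groups).pvalue, rel=1e-9)

    def test_collinear_covariate_rejected(self):
        vals, tert = make_tertiles([1, 2, 3], [2, 3, 4], [3, 4, 5])
        data = pd.DataFrame({"dup": tert.map({"T1": 0, "T2": 1, "T3": 2})})
        # a covariate identical to the tertile coding is rank deficient
        with pytest.raises(ValueError, match="rank deficient"):
            pstats.test_quantitative(vals, tert, data, ["dup"])

    def test_bonferroni_bounds(self, scored):
        res = pstats.test_quantitative(scored["glucose"], scored["tertile"], scored,
                                ["sex", "age"])
        for pair, p in res["pairwise"].items():
            assert 0.0 <= p <= 1.0

    def test_adjustment_changes_p(self, scored):
        plain = pstats.test_quantitative(scored["ltpa_moderate"], scored["tertile"])
        adj = pstats.test_quantitative(scored["ltpa_moderate"], scored["tertile"],
                                scored, ["sex", "age"])
        assert plain["p"] != adj["p"]  # covariates actually entered the model


class TestKruskalWallis:
    def test_hand_value(self):
        vals, tert = make_tertiles([1, 2, 3], [4, 5, 6], [7, 8, 9])
        res = pstats.test_nonparametric(vals, tert)
        assert res["statistic"] == pytest.approx(7.2)
        assert res["p"] == pytest.approx(0.0273, abs=5e-4)

    def test_identical_groups(self):
        vals, tert = make_tertiles([5, 5], [5, 5], [5, 5])
        res = pstats.test_nonparametric(vals, tert)
        assert res["p"] == 1.0

    def test_monotone_transform_invariant(self):
        rng = np.random.default_rng(2)
        vals = pd.Series(rng.gamma(2, 1, 90))
        tert = pd.Series(np.repeat(["T1", "T2", "T3"], 30))
        h1 = pstats.test_nonparametric(vals, tert)["statistic"]
        h2 = pstats.test_nonparametric(np.log(vals + 1), tert)["statistic"]
        assert h1 == pytest.approx(h2, rel=1e-9)

    def test_pairwise_bonferroni_capped(self):
        vals, tert = make_tertiles([1, 2, 3], [1, 2, 3], [1, 2, 3])
        res = pstats.test_nonparametric(vals, tert)
        assert all(p <= 1.0 for p in res["pairwise"].values())


class TestNormalityVariance:
    def test_gross_nonnormality_detected(self):
        rng = np.random.default_rng(3)
        vals = pd.Series(rng.exponential(1.0, 10_000))
        tert = pd.Series(np.repeat(["T1", "T2", "T3"], 10_000 // 3 + 1)[:10_000])
        res = normality_and_variance_checks(vals, tert)
        assert res["ks_p"] < 0.001

    def test_normal_sample_passes(self):
        rng = np.random.default_rng(4)
        vals = pd.Series(rng.normal(0, 1, 5000))
        tert = pd.Series(np.repeat(["T1", "T2", "T3"], 5000 // 3 + 1)[:5000])
        res = normality_and_variance_checks(vals, tert)
        assert res["ks_p"] > 0.01
        assert res["levene_p"] > 0.001

    def test_unequal_variances_detected(self):
        rng = np.random.default_rng(5)
        vals = pd.Series(np.concatenate([rng.normal(0, 1, 500),
                                         rng.normal(0, 4, 500),
                                         rng.normal(0, 1, 500)]))
        tert = pd.Series(np.repeat(["T1", "T2", "T3"], 500))
        assert normality_and_variance_checks(vals, tert)["levene_p"] < 1e-6

    def test_constant_data_flagged_undefined(self):
        vals, tert = make_tertiles([1, 1], [1, 1], [1, 1])
        res = normality_and_variance_checks(vals, tert)
        assert np.isnan(res["ks_p"])


def test_build_tables_shapes_and_pvalues(scored):
    tables = build_tables(scored)
    assert set(tables) == {"table1", "table2", "table3", "table4", "table5"}
    for name in ("table2", "table3", "table4", "table5"):
        t = tables[name]
        assert not t.empty
        for col in ("p_unadjusted", "p_sex_age", "p_full"):
            assert t[col].dropna().between(0, 1).all()
        assert {"T1_mean_sd", "T2_median_iqr"} <= set(t.columns)
    assert "Women" in tables["table1"]["variable"].tolist()
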