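"""Association tests, validity rules, Bonferroni families, recurrence."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from metasub import (
    AssociationResult, associate, bonferroni_families, find_recurrent,
    logrank_test,
)
from metasub.associate import (
    test_categorical as categorical_test,
    test_continuous as continuous_test,
    test_survival as survival_test,
)
from metasub.associate import reduce_contingency


class TestContinuous:
    def test_exact_mann_whitney_small_groups(self):
        # {1,2} vs {3,4}: 2 of the 6 rank arrangements are as extreme
        name, s, p, valid, n, _ = continuous_test(
            np.array([1.0, 2.0, 3.0, 4.0]), np.array([1, 1, 2, 2]))
        assert name == "mann_whitney"
        assert valid
        assert p == pytest.approx(1 / 3)

    def test_constant_values_p_one(self):
        name, s, p, valid, *_ = continuous_test(
            np.full(10, 3.0), np.array([1] * 5 + [2] * 5))
        assert valid and p == 1.0

    def test_three_groups_use_kruskal_wallis(self, rng):
        vals = rng.normal(size=30)
        groups = np.repeat([1, 2, 3], 10)
        name, s, p, valid, *_ = continuous_test(vals, groups)
        assert name == "kruskal_wallis"
        ref = stats.kruskal(vals[:10], vals[10:20], vals[20:])
        assert p == pytest.approx(ref.pvalue)

    def test_empty_cluster_invalid(self):
        vals = np.array([1.0, np.nan, 2.0, np.nan])
        name, s, p, valid, n, reason = continuous_test(
            vals, np.array([1, 2, 1, 2]))
        assert not valid and "empty" in reason

    def test_missing_dropped_pairwise(self, rng):
        vals = np.array([1.0, np.nan, 3.0, 2.0, 5.0, 4.0])
        name, s, p, valid, n, _ = continuous_test(
            vals, np.array([1, 1, 1, 2, 2, 2]))
        assert valid and n == 5


def fisher_oracle(table):
    """Two-sided Fisher by hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        pk = stats.hypergeom.pmf(k, n, r1, c1)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(total, 1.0)


class TestCategorical:
    def test_fisher_hand_value(self):
        labels = np.array(["m"] * 4 + ["w"] * 4)
        clusters = np.array([1, 1, 1, 2, 1, 2, 2, 2])
        name, odds, p, valid, *_ = categorical_test(labels, clusters)
        assert name == "fisher_exact"
        assert p == pytest.approx(34 / 70, abs=1e-6)  # hypergeometric by hand

    def test_perfect_independence(self):
        labels = np.array(["m"] * 10 + ["w"] * 10)
        clusters = np.tile([1, 2], 10)
        name, odds, p, valid, *_ = categorical_test(labels, clusters)
        assert p == pytest.approx(1.0)

    def test_rare_level_removed_then_fisher(self):
        # level C has expected counts ~2 -> removed; A/B leave a 2x2 Fisher
        labels = np.array(["A"] * 60 + ["B"] * 40 + ["C"] * 4)
        clusters = np.array([1] * 30 + [2] * 30 + [1] * 20 + [2] * 20
                            + [1] * 3 + [2] * 1)
        table = pd.crosstab(labels, clusters)
        reduced = reduce_contingency(table)
        assert list(reduced.index) == ["A", "B"]
        name, odds, p, valid, n, _ = categorical_test(labels, clusters)
        assert name == "fisher_exact"
        assert n == 100
        assert p == pytest.approx(fisher_oracle(reduced.to_numpy()), abs=1e-9)

    def test_large_table_chi_square_no_continuity(self, rng):
        labels = rng.choice(["A", "B", "C"], size=300)
        clusters = rng.choice([1, 2, 3], size=300)
        name, s, p, valid, *_ = categorical_test(labels, clusters)
        assert name == "chi_square"
        ref = stats.chi2_contingency(pd.crosstab(labels, clusters),
                                     correction=False)
        assert p == pytest.approx(ref.pvalue)

    def test_single_level_invalid(self):
        name, s, p, valid, n, reason = categorical_test(
            np.array(["A"] * 6), np.array([1, 1, 1, 2, 2, 2]))
        assert not valid


class TestSurvival:
    def test_identical_groups_null(self):
        times = np.tile([50.0, 120.0, 200.0, 300.0, 400.0, 500.0, 77.0,
                         90.0, 150.0, 250.0], 2)
        events = np.tile([1, 1, 1, 1, 1, 0, 1, 1, 1, 1], 2)
        groups = np.repeat([1, 2], 10)
        stat, p, obs, exp = logrank_test(times, events, groups)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_hand_computed_two_group_toy(self):
        # g1 events at t=1,3; g2 events at t=2,4 (no censoring)
        times = np.array([1.0, 3.0, 2.0, 4.0])
        events = np.array([1, 1, 1, 1])
        groups = np.array([1, 1, 2, 2])
        stat, p, obs, exp = logrank_test(times, events, groups)
        # by hand: E1 = 2/4 + 1/3 + 1/2 + 0 = 4/3; V = 1/4 + 2/9 + 1/4
        assert obs[0] == 2
        assert exp[0] == pytest.approx(4 / 3)
        v = 0.25 + 2 / 9 + 0.25
        assert stat == pytest.approx((2 - 4 / 3) ** 2 / v)

    def test_matches_lifelines(self, rng):
        n = 120
        times = rng.exponential(100, size=n)
        events = (rng.random(n) < 0.7).astype(int)
        groups = rng.choice([1, 2, 3], size=n)
        stat, p, *_ = logrank_test(times, events, groups)
        ref = multivariate_logrank_test(times, groups, events)
        assert stat == pytest.approx(ref.test_statistic, rel=1e-8)
        assert p == pytest.approx(ref.p_value, rel=1e-8)

    def test_relabeling_invariant(self, rng):
        n = 80
        times = rng.exponential(100, size=n)
        events = (rng.random(n) < 0.6).astype(int)
        groups = rng.choice([1, 2], size=n)
        s1, p1, *_ = logrank_test(times, events, groups)
        s2, p2, *_ = logrank_test(times, events, 3 - groups)
        assert s1 == pytest.approx(s2)

    def test_low_expected_events_invalid(self, rng):
        times = np.concatenate([rng.exponential(10, 50),
                                rng.exponential(10, 4)])
        events = np.ones(54, dtype=int)
        events[50:] = 0  # tiny group contributes almost no expected events
        groups = np.array([1] * 50 + [2] * 4)
        name, s, p, valid, n, reason = survival_test(times, events, groups)
        assert not valid
        assert "expected events" in reason

    def test_no_events_invalid(self):
        name, s, p, valid, n, reason = survival_test(
            np.arange(1.0, 11.0), np.zeros(10), np.repeat([1, 2], 5))
        assert not valid and reason == "no events"


def make_result(cls, p, valid=True, tumor="BRCA", feature="f", gene_set="GS"):
    return AssociationResult(
        tumor_type=tumor, gene_set=gene_set, collection="c",
        variable_class=cls, feature=feature, test="mann_whitney", k=2,
        statistic=1.0, p_value=p, valid=valid, n_used=50)


class TestBonferroni:
    def test_threshold_scales_with_family_size(self):
        results = [make_result("mirna", 4e-5, feature=f"m{i}")
                   for i in range(1000)]
        bonferroni_families(results)
        assert results[0].significant  # 4e-5 < 0.05/1000
        results = [make_result("mirna", 4e-5, feature=f"m{i}")
                   for i in range(2000)]
        bonferroni_families(results)
        assert not results[0].significant  # 4e-5 > 0.05/2000

    def test_invalid_excluded_from_family(self):
        results = [make_result("mirna", 1e-3, feature="a"),
                   make_result("mirna", np.nan, valid=False, feature="b")]
        fams = bonferroni_families(results)
        assert fams[0].m == 1
        assert results[0].significant
        assert not results[1].significant
        fams = bonferroni_families(results, count_invalid=True)
        assert fams[0].m == 2

    def test_lower_alpha_never_more_significant(self, rng):
        results = [make_result("mirna", p, feature=f"m{i}")
                   for i, p in enumerate(rng.random(200) * 1e-3)]
        bonferroni_families(results, alpha=0.05)
        n_high = sum(r.significant for r in results)
        bonferroni_families(results, alpha=0.01)
        n_low = sum(r.significant for r in results)
        assert n_low <= n_high


class TestRecurrent:
    def base_results(self):
        rs = [make_result("gene_mutation", 1e-9, tumor=t, feature="TP53")
              for t in ("BRCA", "LUAD")]
        rs += [make_result("mirna", 1e-9, tumor=t, feature="mir-1")
               for t in ("LUAD", "LUNG")]
        for r in rs:
            r.significant = True
        return rs

    def test_two_tumor_types_recur(self):
        out = find_recurrent(self.base_results())
        assert len(out) == 1
        row = out.iloc[0]
        assert row["feature"] == "TP53"
        assert row["n_tumor_types"] == 2
        assert row["tumor_types"] == "BRCA;LUAD"

    def test_composite_types_excluded(self):
        out = find_recurrent(self.base_results())
        assert "mir-1" not in out["feature"].tolist()  # LUNG is composite

    def test_empty(self):
        assert len(find_recurrent([])) == 0


class TestAssociateDispatch:
    def test_demo_cohort_planted_effects_significant(self, demo_cohort):
        from metasub import cluster_gene_set
        from metasub.pipeline import cohort_tables
        spec, cohort = demo_cohort
        sol = cluster_gene_set(cohort.expression,
                               spec.gene_sets["PATHWAY_A_METABOLISM"],
                               tumor_type="DEMO")
        tables = cohort_tables(cohort, seed=7)
        results = associate(sol, tables)
        bonferroni_families(results)
        sig = {(r.variable_class, r.feature) for r in results if r.significant}
        assert ("gene_mutation", "MUTA") in sig
        assert ("mirna", "mir-900") in sig
        assert ("copy_number", "reg_1_1") in sig
        assert ("methylation_global", "global_methylation") in sig
        assert ("overall_survival", "overall_survival") in sig
        assert ("clinical", "histology") in sig
        assert ("protein_rppa", "PROTA") in sig
        # the null recurrence-free endpoint must not light up
        assert ("recurrence_free_survival", "recurrence_free_survival") not in sig

    def test_gated_out_solution_yields_no_tests(self, demo_cohort):
        from metasub import cluster_gene_set
        from metasub.pipeline import cohort_tables
        spec, cohort = demo_cohort
        sol = cluster_gene_set(cohort.expression,
                               spec.gene_sets["PATHWAY_B_METABOLISM"])
        assert associate(sol, cohort_tables(cohort, seed=7)) == []
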