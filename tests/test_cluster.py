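"""Subtype clustering: transforms, Duda-Hart gate, PAM, silhouette,
k selection, NMI, and differential genes."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from sklearn.metrics import adjusted_rand_score, silhouette_samples
from sklearn.metrics import normalized_mutual_info_score

from metasub import (
    GeneSet, cluster_gene_set, differential_genes, duda_hart_test,
    log_transform, nmi, pam_cluster, pam_objective, rank_transform, select_k,
    silhouette_width, spearman_distance,
)
from metasub.cluster import UnusablePairError


def frame(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestTransforms:
    @pytest.mark.parametrize("row, expected", [
        ([5, 1, 3], [3, 1, 2]),
        ([2, 2, 7], [1.5, 1.5, 3]),
        ([4, 4, 4], [2, 2, 2]),
    ])
    def test_rank_rows(self, row, expected):
        ranked, flat = rank_transform(frame([row]))
        assert ranked.iloc[0].tolist() == expected

    def test_constant_row_flagged(self):
        _, flat = rank_transform(frame([[4, 4, 4], [1, 2, 3]]))
        assert flat == ["G0"]

    def test_log_transform(self):
        out = log_transform(frame([[0, 7]]), pseudocount=1)
        assert out.iloc[0].tolist() == [0.0, 3.0]

    def test_log_transform_rejects_negative(self):
        with pytest.raises(ValueError):
            log_transform(frame([[-1, 2]]))


class TestSpearmanDistance:
    def test_identical_profiles_zero(self):
        expr = frame([[1, 1, 9], [5, 5, 2], [2, 2, 4], [9, 9, 1]])
        d = spearman_distance(expr)
        assert d.iloc[0, 1] == pytest.approx(0.0)
        assert d.iloc[0, 2] > 0

    def test_reversed_ranks_two(self):
        expr = frame([[1, 4], [2, 3], [3, 2], [4, 1]])
        d = spearman_distance(expr)
        assert d.iloc[0, 1] == pytest.approx(2.0)

    def test_matches_scipy_spearman(self, rng):
        expr = frame(rng.normal(size=(6, 4)))
        d = spearman_distance(expr)
        for i, j in itertools.combinations(range(4), 2):
            rho = stats.spearmanr(expr.iloc[:, i], expr.iloc[:, j]).statistic
            assert d.iloc[i, j] == pytest.approx(1 - rho)

    def test_gene_subset_and_zero_variance_drop(self, rng):
        expr = frame(np.vstack([rng.normal(size=(4, 5)), np.ones((1, 5))]),
                     genes=["A", "B", "C", "D", "FLAT"])
        gs = GeneSet(name="S", genes=frozenset({"A", "B", "FLAT"}))
        d = spearman_distance(expr, gs)
        assert d.shape == (5, 5)

    def test_too_few_genes_unusable(self, rng):
        expr = frame(rng.normal(size=(3, 4)))
        gs = GeneSet(name="S", genes=frozenset({"G0"}))
        with pytest.raises(UnusablePairError):
            spearman_distance(expr, gs)


class TestDudaHart:
    def test_separated_blobs_reject(self, rng):
        pts = np.vstack([rng.normal(0, 0.1, size=(20, 3)),
                         rng.normal(50, 0.1, size=(20, 3))])
        split = np.repeat([0, 1], 20)
        h, p = duda_hart_test(pts, split)
        assert h < 0.01
        assert p < 1e-6

    def test_statistic_matches_hand_formula(self, rng):
        pts = rng.normal(size=(12, 4))
        split = np.array([0, 1] * 6)
        h, p = duda_hart_test(pts, split)
        je1 = ((pts - pts.mean(0)) ** 2).sum()
        je2 = sum(((pts[split == s] - pts[split == s].mean(0)) ** 2).sum()
                  for s in (0, 1))
        assert h == pytest.approx(je2 / je1)
        n, d = pts.shape
        z = (1 - 2 / (np.pi * d) - h) * np.sqrt(
            n * d / (2 * (1 - 8 / (np.pi ** 2 * d))))
        assert p == pytest.approx(stats.norm.sf(z))

    def test_identical_points_degenerate(self):
        pts = np.ones((6, 3))
        with pytest.raises(ValueError, match="degenerate"):
            duda_hart_test(pts, np.array([0, 0, 0, 1, 1, 1]))

    def test_single_part_rejected(self, rng):
        pts = rng.normal(size=(6, 3))
        with pytest.raises(ValueError, match="two"):
            duda_hart_test(pts, np.zeros(6))


def euclid_1d(points):
    pts = np.asarray(points, dtype=float)
    return np.abs(pts[:, None] - pts[None, :])


def brute_force_pam(d, k):
    n = d.shape[0]
    best = None
    for med in itertools.combinations(range(n), k):
        obj = d[:, med].min(axis=1).sum()
        if best is None or obj < best[0] - 1e-12:
            best = (obj, med)
    return best


class TestPam:
    def test_two_blobs_1d(self):
        d = euclid_1d([0, 1, 2, 10, 11, 12])
        med, labels = pam_cluster(d, 2)
        assert med.tolist() == [1, 4]
        assert labels.tolist() == [1, 1, 1, 2, 2, 2]

    def test_k_equals_n_minus_1(self):
        pts = [0.0, 1.0, 3.0, 7.0, 15.0]
        d = euclid_1d(pts)
        med, labels = pam_cluster(d, 4)
        obj = pam_objective(d, med)
        off_diag = d[np.triu_indices(5, k=1)]
        assert obj == pytest.approx(off_diag.min())

    def test_duplicate_points_deterministic(self):
        d = euclid_1d([0, 0, 0, 5, 5, 5])
        med1, lab1 = pam_cluster(d, 2)
        med2, lab2 = pam_cluster(d, 2)
        assert med1.tolist() == med2.tolist() == [0, 3]
        assert lab1.tolist() == lab2.tolist()

    def test_invalid_k(self):
        d = euclid_1d([0, 1, 2])
        with pytest.raises(ValueError):
            pam_cluster(d, 1)
        with pytest.raises(ValueError):
            pam_cluster(d, 3)

    def test_never_beats_brute_force(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 9))
            x = rng.normal(size=(n, 2))
            d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
            for k in (2, 3):
                med, _ = pam_cluster(d, k)
                opt, _ = brute_force_pam(d, k)
                assert pam_objective(d, med) >= opt - 1e-9


class TestSilhouette:
    def test_hand_example(self):
        d = euclid_1d([0, 0.1, 10, 10.1])
        labels = np.array([1, 1, 2, 2])
        per, avg = silhouette_width(d, labels)
        # point 0: a = 0.1, b = (10 + 10.1)/2 = 10.05 -> s = 9.95/10.05
        assert per[0] == pytest.approx((10.05 - 0.1) / 10.05)
        assert avg == pytest.approx(0.990, abs=5e-4)

    def test_matches_sklearn(self, rng):
        x = rng.normal(size=(20, 3))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        labels = np.array([1, 2, 3] * 6 + [1, 2])
        per, avg = silhouette_width(d, labels)
        ref = silhouette_samples(d, labels, metric="precomputed")
        np.testing.assert_allclose(per, ref, atol=1e-10)

    def test_identical_points_and_singletons(self):
        d = np.zeros((4, 4))
        per, avg = silhouette_width(d, np.array([1, 1, 2, 2]))
        assert avg == 0.0
        d2 = euclid_1d([0, 5])
        per2, avg2 = silhouette_width(d2, np.array([1, 2]))
        assert avg2 == 0.0

    def test_range_invariant(self, rng):
        x = rng.normal(size=(15, 4))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        _, labels = pam_cluster(d, 4)
        per, avg = silhouette_width(d, labels)
        assert np.all(per >= -1) and np.all(per <= 1)
        assert -1 <= avg <= 1


class TestSelectK:
    def test_three_blobs(self, rng):
        pts = np.concatenate([rng.normal(c, 0.1, size=10) for c in (0, 20, 50)])
        k, med, labels, asw = select_k(euclid_1d(pts))
        assert k == 3

    def test_two_blobs(self, rng):
        pts = np.concatenate([rng.normal(c, 0.2, size=12) for c in (0, 30)])
        k, *_ = select_k(euclid_1d(pts))
        assert k == 2

    def test_tie_prefers_smaller_k(self):
        # all points equidistant: ASW = 0 for every k -> k = 2 wins the tie
        d = np.ones((5, 5)) - np.eye(5)
        k, *_ = select_k(d)
        assert k == 2

    def test_k_max_clamped_to_n_minus_1(self, rng):
        d = euclid_1d(rng.normal(size=6))
        k, *_ = select_k(d, k_max=10)
        assert 2 <= k <= 5


class TestNmi:
    def test_identical_partitions(self):
        assert nmi([1, 1, 2, 2], [1, 1, 2, 2]) == pytest.approx(1.0)

    def test_independent_partitions(self):
        assert nmi([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # joint counts {(1,1):2, (2,1):1, (2,2):1}; I = 0.21576 nats,
        # H(A) = ln 2, H(B) = 0.56234 -> NMI = 0.34559
        a, b = [1, 1, 2, 2], [1, 1, 1, 2]
        assert nmi(a, b) == pytest.approx(0.34559, abs=1e-4)
        ref = normalized_mutual_info_score(a, b, average_method="geometric")
        assert nmi(a, b) == pytest.approx(ref)

    def test_single_cluster_zero(self):
        assert nmi([1, 1, 1], [1, 2, 2]) == 0.0

    def test_sample_mismatch(self):
        with pytest.raises(ValueError):
            nmi([1, 2], [1, 2, 3])

    @given(st.lists(st.integers(0, 3), min_size=4, max_size=30),
           st.data())
    @settings(deadline=None, derandomize=True)
    def test_symmetry_and_label_permutation(self, a, data):
        b = data.draw(st.lists(st.integers(0, 3), min_size=len(a),
                               max_size=len(a)))
        assert nmi(a, b) == pytest.approx(nmi(b, a))
        remap = {0: 7, 1: 5, 2: 9, 3: 2}
        assert nmi([remap[x] for x in a], b) == pytest.approx(nmi(a, b))
        if len(set(a)) >= 2:
            assert nmi(a, a) == pytest.approx(1.0)


class TestDifferentialGenes:
    def test_constant_gene_p_one(self):
        expr = frame([[1, 1, 1, 1], [1, 2, 8, 9]])
        assign = pd.Series([1, 1, 2, 2], index=expr.columns)
        out = differential_genes(expr, assign, top_n=5)
        assert out.set_index("gene").loc["G0", "p_value"] == 1.0

    def test_perfect_separation_matches_exact_kw(self):
        # 10 vs 10 with complete separation: H = 12/(N(N+1)) * sum n(Rbar - (N+1)/2)^2
        values = np.arange(1, 21, dtype=float)
        expr = frame([values])
        assign = pd.Series([1] * 10 + [2] * 10, index=expr.columns)
        out = differential_genes(expr, assign)
        h = 12 / (20 * 21) * (10 * (5.5 - 10.5) ** 2 + 10 * (15.5 - 10.5) ** 2)
        assert out["p_value"][0] == pytest.approx(stats.chi2.sf(h, df=1))

    def test_top_n_larger_than_gene_count(self, rng):
        expr = frame(rng.normal(size=(3, 8)))
        assign = pd.Series([1, 1, 1, 1, 2, 2, 2, 2], index=expr.columns)
        assert len(differential_genes(expr, assign, top_n=20)) == 3


class TestClusterGeneSet:
    def test_planted_structure_recovered(self, demo_cohort):
        spec, cohort = demo_cohort
        gs = spec.gene_sets["PATHWAY_A_METABOLISM"]
        sol = cluster_gene_set(cohort.expression, gs, tumor_type="DEMO")
        assert sol.clustered and sol.passed_gate
        assert sol.k == 2
        truth = np.array(cohort.truth["assignments"]["PATHWAY_A_METABOLISM"])
        assert adjusted_rand_score(truth, sol.assignments.to_numpy()) == 1.0

    def test_null_gene_set_gated_out(self, demo_cohort):
        spec, cohort = demo_cohort
        gs = spec.gene_sets["PATHWAY_B_METABOLISM"]
        sol = cluster_gene_set(cohort.expression, gs)
        assert sol.status == "gated_out"
        assert not sol.passed_gate

    def test_unusable_gene_set(self, demo_cohort):
        _, cohort = demo_cohort
        gs = GeneSet(name="TINY", genes=frozenset({"GA001", "NOT_PRESENT"}))
        sol = cluster_gene_set(cohort.expression, gs)
        assert sol.status == "unusable"

    def test_deterministic(self, demo_cohort):
        spec, cohort = demo_cohort
        gs = spec.gene_sets["PATHWAY_A_METABOLISM"]
        a = cluster_gene_set(cohort.expression, gs)
        b = cluster_gene_set(cohort.expression, gs)
        assert a.assignments.equals(b.assignments)
        assert a.medoids == b.medoids
        assert a.duda_hart_p == b.duda_hart_p
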