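"""Differential expression: test branching, exactness, FDR, QC, structure."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from rbdge.de import (
    CohortError,
    bh_adjust,
    choose_test,
    cluster,
    correlation_analysis,
    de_test,
    log2_fold_change,
    mean_variance_qc,
    pca,
    run_de,
)
from rbdge.normalization import normalize_pipeline
from rbdge.simulate import SimulationConfig, simulate_dataset


def exact_rank_sum_p(a, b):
    """Brute-force two-sided Wilcoxon p by enumerating all labelings."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    obs = ranks[: len(a)].sum()
    # two-sided via distance from the mean rank sum
    mean = len(a) * (n + 1) / 2.0
    hits = total = 0
    for idx in combinations(range(n), len(a)):
        s = ranks[list(idx)].sum()
        total += 1
        if abs(s - mean) >= abs(obs - mean) - 1e-12:
            hits += 1
    return hits / total


class TestChooseTest:
    def test_normal_looking_groups_go_parametric(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        choice, pa, pb = choose_test(a, a)
        assert choice == "student_t"
        assert pa == pytest.approx(0.967, abs=0.01)  # Shapiro p for 1..5

    def test_normal_quantiles_go_parametric(self):
        q = stats.norm.ppf(np.linspace(0.05, 0.95, 10))
        choice, pa, pb = choose_test(q, q + 1.0)
        assert choice == "student_t"
        assert pa > 0.9 and pb > 0.9

    def test_constant_group_forces_rank_test(self):
        choice, pa, _ = choose_test([2.0] * 5, [1.0, 2.0, 3.0, 4.0, 5.0])
        assert choice == "wilcoxon"
        assert np.isnan(pa)

    def test_tiny_group_forces_rank_test(self):
        choice, pa, _ = choose_test([1.0, 2.0], [1.0, 2.0, 3.0])
        assert choice == "wilcoxon"
        assert np.isnan(pa)

    def test_skewed_group_forces_rank_test(self):
        skewed = [1.0, 1.01, 1.02, 1.03, 1.04, 1.05, 1.1, 2.0, 50.0, 400.0]
        choice, _, _ = choose_test(skewed, list(range(10)))
        assert choice == "wilcoxon"


class TestDeTest:
    def test_exact_wilcoxon_small_separated_groups(self):
        used, u, p = de_test([1, 2, 3], [4, 5, 6], "wilcoxon")
        assert used == "wilcoxon"
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/C(6,3)

    def test_identical_groups_give_p_one(self):
        _, _, p = de_test([3, 3, 3], [3, 3, 3], "wilcoxon")
        assert p == 1.0

    def test_degenerate_parametric_input_reroutes_to_rank_test(self):
        used, _, p = de_test([0, 0, 0], [5, 5, 5], "student_t")
        assert used == "wilcoxon"
        assert p < 0.2  # defined, no exception

    def test_student_branch_is_pooled_variance(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 6)
        _, t, p = de_test(a, b, "student_t")
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_swap_symmetry(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(0.5, 1, 7)
        _, _, p1 = de_test(a, b, "wilcoxon")
        _, _, p2 = de_test(b, a, "wilcoxon")
        assert p1 == pytest.approx(p2)
        assert log2_fold_change(a + 2, b + 2) == pytest.approx(
            -log2_fold_change(b + 2, a + 2)
        )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(st.integers(0, 10_000), min_size=2, max_size=5),
        st.lists(st.integers(0, 10_000), min_size=2, max_size=5),
    )
    def test_exact_branch_matches_enumeration(self, a, b):
        a, b = np.array(a, float), np.array(b, float)
        pooled = np.concatenate([a, b])
        if np.unique(pooled).size != pooled.size or np.ptp(pooled) == 0:
            return  # exact branch is tie-free by contract
        _, _, p = de_test(a, b, "wilcoxon")
        assert p == pytest.approx(exact_rank_sum_p(a, b), abs=1e-9)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.5], [0.5]),
            ([0.005, 0.5], [0.01, 0.5]),
        ],
    )
    def test_step_up_examples(self, p, expected):
        assert np.allclose(bh_adjust(np.array(p)), expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_monotone_and_bounded(self, p):
        p = np.array(p)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)  # order-preserving

    def test_matches_manual_step_up(self, rng):
        p = rng.uniform(size=15)
        order = np.argsort(p)
        sorted_p = p[order]
        m = len(p)
        manual = np.minimum.accumulate(
            (sorted_p * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        manual = np.minimum(manual, 1.0)
        q = bh_adjust(p)
        assert np.allclose(q[order], manual)


class TestFoldChange:
    def test_pseudocount_arithmetic(self):
        assert log2_fold_change([15, 15], [3, 3]) == pytest.approx(2.0)
        assert log2_fold_change([7, 7], [7, 7]) == 0.0
        assert log2_fold_change([0, 0], [0, 0]) == 0.0


class TestRunDE:
    def test_recovers_truth_with_good_error_control(self):
        """Sensitivity and FDR on a default-strength cohort."""
        ds = simulate_dataset(SimulationConfig(seed=1))
        norm, _, _, calls, _ = normalize_pipeline(ds.counts)
        de = run_de(norm, ds.annotations, calls)
        sig = set(de[de.significant].gene)
        truth = ds.truth.loc[de.gene]
        true_de = set(truth[truth.is_de].index)
        sens = len(sig & true_de) / len(true_de)
        fdr = len(sig - true_de) / max(len(sig), 1)
        assert sens >= 0.6
        assert fdr <= 0.10

    def test_below_noise_genes_are_absent(self, small_dataset):
        norm, _, _, calls, _ = normalize_pipeline(small_dataset.counts)
        de = run_de(norm, small_dataset.annotations, calls)
        below = {c.gene for c in calls if not c.above_noise}
        assert below
        assert not (set(de.gene) & below)
        assert set(de.gene) == {c.gene for c in calls if c.above_noise}

    def test_missing_subtype_is_cohort_error(self, small_dataset):
        urb_only = [a for a in small_dataset.annotations if a.subtype == "URB"]
        norm, _, _, calls, _ = normalize_pipeline(small_dataset.counts)
        with pytest.raises(CohortError):
            run_de(norm, urb_only, calls)

    def test_result_sorted_by_q_then_effect(self, small_dataset):
        norm, _, _, calls, _ = normalize_pipeline(small_dataset.counts)
        de = run_de(norm, small_dataset.annotations, calls)
        q = de.q_fdr.to_numpy()
        assert np.all(np.diff(q) >= -1e-12)


class TestQC:
    def test_common_dispersion_yields_few_outliers(self):
        # null cohort: every gene shares the NB dispersion, so nothing
        # should sit off the mean-variance trend
        ds = simulate_dataset(
            SimulationConfig(de_fraction=0.0, background_fraction=0.0, seed=0)
        )
        qc = mean_variance_qc(ds.counts)
        assert len(qc.outlier_genes) / 770 <= 0.02
        assert np.allclose(np.diag(qc.correlation), 1.0)
        assert qc.correlation.to_numpy().min() >= -1.0

    def test_injected_variance_outlier_is_flagged(self, rng):
        ds = simulate_dataset(SimulationConfig(n_endogenous=100, seed=4))
        m = ds.counts
        endo = m.rows_of_class("Endogenous")
        target = endo[0]
        noisy = m.values.copy()
        mid = noisy[target].mean()
        noisy[target] = mid + (noisy[target] - mid) * 10 + rng.normal(0, mid, noisy.shape[1])
        noisy = np.clip(noisy, 0, None)
        qc = mean_variance_qc(m.copy_with(noisy))
        assert m.codeset.probes[target].name in qc.outlier_genes

    def test_identical_genes_give_zero_outliers(self):
        from tests_support import constant_matrix

        qc = mean_variance_qc(constant_matrix(value=50.0, n_genes=5, n_samples=4))
        assert qc.outlier_genes == []
        assert qc.outlier_samples == []


class TestCorrelation:
    def test_identity_is_perfect(self):
        r, _ = correlation_analysis([1, 2, 3, 4], [1, 2, 3, 4], "pearson")
        rho, _ = correlation_analysis([1, 2, 3, 4], [1, 2, 3, 4], "spearman")
        assert r == pytest.approx(1.0)
        assert rho == pytest.approx(1.0)

    def test_monotone_nonlinearity_separates_methods(self):
        x = np.arange(1.0, 11.0)
        y = x**3
        rho, _ = correlation_analysis(x, y, "spearman")
        r, _ = correlation_analysis(x, y, "pearson")
        assert rho == pytest.approx(1.0)
        assert r < 1.0

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError):
            correlation_analysis([1, 2, 3], [5, 5, 5], "pearson")


class TestPCA:
    def test_two_distinct_samples_have_one_component(self):
        from tests_support import two_sample_matrix

        res = pca(two_sample_matrix())
        assert res.variance_fractions[0] == pytest.approx(1.0)

    def test_identical_samples_give_zero_scores(self):
        from tests_support import constant_matrix

        res = pca(constant_matrix(value=20.0, n_genes=6, n_samples=4))
        assert np.allclose(res.scores.to_numpy(), 0.0)

    def test_strong_de_separates_subtypes_on_pc1(self):
        ds = simulate_dataset(SimulationConfig(de_fraction=0.3, lfc_magnitude=3.0, seed=8))
        norm, _, _, _, _ = normalize_pipeline(ds.counts)
        tumor = norm.subset_samples(norm.sample_ids[:21])
        res = pca(tumor)
        labels = np.array([1.0] * 11 + [0.0] * 10)
        r = np.corrcoef(res.scores["PC1"], labels)[0, 1]
        assert abs(r) > 0.8


class TestCluster:
    def test_duplicated_samples_merge_at_height_zero(self):
        from tests_support import duplicated_pair_matrix

        res = cluster(duplicated_pair_matrix())
        assert res.linkage_matrix[0, 2] == pytest.approx(0.0)

    def test_supervised_never_interleaves_subtypes(self, small_dataset):
        norm, _, _, _, _ = normalize_pipeline(small_dataset.counts)
        res = cluster(norm, mode="supervised", annotations=small_dataset.annotations)
        by_id = {a.sample_id: a.subtype for a in small_dataset.annotations}
        seen = [by_id[s] for s in res.leaf_order]
        # each subtype occupies one contiguous block
        blocks = [s for i, s in enumerate(seen) if i == 0 or s != seen[i - 1]]
        assert len(blocks) == len(set(seen))

    def test_strong_de_recovers_subtypes_at_two_clusters(self):
        from scipy.cluster.hierarchy import fcluster

        ds = simulate_dataset(SimulationConfig(de_fraction=0.3, lfc_magnitude=3.0, seed=8))
        norm, _, _, _, _ = normalize_pipeline(ds.counts)
        tumor = norm.subset_samples(norm.sample_ids[:21])
        res = cluster(tumor)
        assign = fcluster(res.linkage_matrix, 2, criterion="maxclust")
        truth = np.array([1] * 11 + [2] * 10)
        same_truth = truth[:, None] == truth[None, :]
        same_pred = assign[:, None] == assign[None, :]
        iu = np.triu_indices(21, k=1)
        rand = (same_truth == same_pred)[iu].mean()
        assert rand > 0.8

    def test_unknown_linkage_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            cluster(small_dataset.counts, method="bogus")
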