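import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import silhouette_score

from gutflux.stats import (
    ClusterResult,
    bh_fdr,
    cluster_phenotype_association,
    co_clustering_agreement,
    compare_diets,
    differential_metabolites,
    fisher_exact_2x2,
    kmeans_cluster,
    pca_project,
    proportionality,
    ranksum,
    select_high_low_clusters,
    select_k,
)
from helpers import (
    bh_adjust_bruteforce,
    fisher_two_sided_exact,
    ranksum_two_sided_exact,
)


def _blobs(centers, n_per, spread=0.05, seed=0, n_features=2):
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for i, (c, n) in enumerate(zip(centers, n_per)):
        rows.append(rng.normal(c, spread, size=(n, n_features)))
        labels += [i] * n
    X = np.vstack(rows)
    idx = [f"s{i:03d}" for i in range(len(X))]
    return pd.DataFrame(X, index=idx), pd.Series(labels, index=idx)


class TestKMeans:
    def test_separated_blobs_partition(self):
        X = pd.DataFrame({"v": [0.0, 0.1, 10.0, 10.1]}, index=list("abcd"))
        result = kmeans_cluster(X, k=2, replicates=10, seed=0)
        a = result.assignments
        assert a["a"] == a["b"] and a["c"] == a["d"] and a["a"] != a["c"]

    def test_duplicate_rows_share_a_cluster(self):
        X, _ = _blobs([0.0, 5.0], [5, 5], seed=1)
        X.loc["dup1"] = X.iloc[0]
        X.loc["dup2"] = X.iloc[0]
        result = kmeans_cluster(X, k=2, replicates=10, seed=0)
        assert result.assignments["dup1"] == result.assignments["dup2"]

    def test_clusters_relabeled_by_descending_size(self):
        X, _ = _blobs([0.0, 5.0], [8, 3], seed=2)
        result = kmeans_cluster(X, k=2, replicates=10, seed=0)
        sizes = result.assignments.value_counts()
        assert sizes[0] >= sizes[1]

    def test_best_of_replicates_objective(self):
        X, _ = _blobs([0.0, 3.0, 6.0, 9.0], [10, 10, 10, 10], spread=1.0, seed=3)
        single = kmeans_cluster(X, k=4, replicates=1, seed=0)
        multi = kmeans_cluster(X, k=4, replicates=50, seed=0)
        assert multi.inertia <= single.inertia + 1e-9

    def test_k_larger_than_n_rejected(self):
        X = pd.DataFrame({"v": [0.0, 1.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            kmeans_cluster(X, k=3)

    def test_phenotype_counts_bookkeeping(self):
        X, truth = _blobs([0.0, 8.0], [6, 4], seed=4)
        phen = pd.Series(
            ["gouty" if t == 0 else "healthy" for t in truth], index=X.index
        )
        result = kmeans_cluster(X, k=2, replicates=10, seed=0, phenotype=phen)
        assert result.phenotype_counts.values.sum() == 10


class TestSelectK:
    def test_three_blobs_select_three(self):
        X, _ = _blobs([0.0, 5.0, 10.0], [10, 12, 8], seed=5)
        best, scores = select_k(X, (2, 5), replicates=20, seed=0)
        assert best == 3
        assert scores.idxmax() == 3

    def test_two_blobs_select_two(self):
        X, _ = _blobs([0.0, 6.0], [10, 10], seed=6)
        best, _ = select_k(X, (2, 4), replicates=20, seed=0)
        assert best == 2

    def test_perfect_partition_beats_random_partition(self):
        X, truth = _blobs([0.0, 6.0], [10, 10], seed=7)
        rng = np.random.default_rng(0)
        random_labels = rng.permutation(truth.values)
        good = silhouette_score(X.values, truth.values, metric="manhattan")
        bad = silhouette_score(X.values, random_labels, metric="manhattan")
        assert good > bad

    def test_degenerate_matrix_rejected(self):
        X = pd.DataFrame(np.ones((5, 3)), index=[f"s{i}" for i in range(5)])
        with pytest.raises(ValueError):
            select_k(X, (2, 3))


class TestPCA:
    def test_rank_one_data_explained_by_first_component(self):
        base = np.arange(6, dtype=float)
        X = pd.DataFrame(np.outer(base, [1.0, 2.0, -1.0]))
        _, evr = pca_project(X, n_components=1)
        assert evr[0] == pytest.approx(1.0)

    def test_full_rank_projection_preserves_distances(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(10, 3)))
        scores, _ = pca_project(X, n_components=3)
        from scipy.spatial.distance import pdist

        assert np.allclose(pdist(X.values), pdist(scores.values), atol=1e-9)

    def test_explained_variance_fractions_sorted_and_bounded(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(20, 5)))
        _, evr = pca_project(X, n_components=4)
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1.0 + 1e-9

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            pca_project(pd.DataFrame(np.full((4, 2), 3.0)))


class TestFisherExact:
    def test_high_vs_low_cluster_contingency(self):
        # 22/26 gouty vs 11/44 gouty
        assert fisher_exact_2x2([[22, 4], [11, 33]]).p_value < 1e-5

    def test_low_vs_small_cluster_contingency(self):
        # 33/44 healthy vs 2/8 healthy
        assert fisher_exact_2x2([[33, 11], [2, 6]]).p_value == pytest.approx(
            0.011, abs=5e-4
        )

    def test_balanced_table_has_no_association(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]).p_value == 1.0

    def test_zero_margin_flagged_with_p_one(self):
        result = fisher_exact_2x2([[0, 0], [3, 5]])
        assert result.p_value == 1.0 and result.zero_margin

    def test_non_integer_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1.5, 2], [3, 4]])

    def test_matches_exact_enumeration_oracle(self):
        for a in range(4):
            for b in range(4):
                for c in range(3):
                    for d in range(3):
                        if min(a + b, c + d, a + c, b + d) == 0:
                            continue
                        ours = fisher_exact_2x2([[a, b], [c, d]]).p_value
                        oracle = float(fisher_two_sided_exact([[a, b], [c, d]]))
                        assert ours == pytest.approx(oracle, abs=1e-9), (a, b, c, d)


class TestRankSum:
    def test_fully_separated_small_samples(self):
        # 2 of the 20 equally likely rank assignments are this extreme
        assert ranksum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples(self):
        assert ranksum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_constant_data(self):
        assert ranksum([5.0, 5.0], [5.0, 5.0, 5.0]) == 1.0

    def test_matches_enumeration_oracle_without_ties(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            nx, ny = rng.integers(2, 7, size=2)
            x = rng.normal(size=nx)
            y = rng.normal(loc=rng.normal(), size=ny)
            assert ranksum(x, y) == pytest.approx(
                ranksum_two_sided_exact(x, y), abs=1e-9
            )

    def test_exact_and_approximate_agree_at_moderate_n(self):
        rng = np.random.default_rng(11)
        from scipy.stats import mannwhitneyu

        for shift in (0.0, 0.5, 1.0, 2.0):
            x = rng.normal(size=10)
            y = rng.normal(loc=shift, size=10)
            exact = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            approx = mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
            assert abs(exact - approx) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ranksum([], [1.0])


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_staircase(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_bruteforce_definition(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            p = rng.uniform(size=rng.integers(1, 9))
            assert np.allclose(bh_fdr(p), bh_adjust_bruteforce(p), atol=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_q_dominates_p_and_stays_in_unit_interval(self, p):
        q = bh_fdr(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all(q <= 1.0)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestProportionality:
    def test_scaled_vector_is_perfectly_proportional(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert proportionality(x, 3 * x) == pytest.approx(1.0)

    def test_reciprocal_vector_is_antiproportional(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert proportionality(x, 1 / x) == pytest.approx(-1.0)

    def test_matches_direct_formula_on_random_vectors(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            x = rng.uniform(0.1, 10, size=12)
            y = rng.uniform(0.1, 10, size=12)
            lx, ly = np.log(x), np.log(y)
            expected = 2 * np.cov(lx, ly, ddof=1)[0, 1] / (
                lx.var(ddof=1) + ly.var(ddof=1)
            )
            assert proportionality(x, y) == pytest.approx(expected, abs=1e-12)
            assert -1.0 <= proportionality(x, y) <= 1.0

    def test_zeros_replaced_by_half_minimum_pseudocount(self):
        x = np.array([0.0, 2.0, 4.0, 8.0])
        y = np.array([1.0, 2.0, 4.0, 8.0])
        with_default = proportionality(x, y)
        with_explicit = proportionality(x, y, pseudocount=0.5)
        assert with_default == pytest.approx(with_explicit)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="variance"):
            proportionality([2.0, 2.0, 2.0], [3.0, 3.0, 3.0])


class TestDifferentialScreen:
    def _matrix(self, means_a, means_b, n=12, seed=0):
        rng = np.random.default_rng(seed)
        mets = [f"m{i}" for i in range(len(means_a))]
        rows_a = rng.normal(means_a, 0.5, size=(n, len(mets))).clip(min=0)
        rows_b = rng.normal(means_b, 0.5, size=(n, len(mets))).clip(min=0)
        idx = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        X = pd.DataFrame(np.vstack([rows_a, rows_b]), index=idx, columns=mets)
        groups = pd.Series(["a"] * n + ["b"] * n, index=idx)
        return X, groups

    def test_large_separated_metabolite_is_flagged(self):
        X, groups = self._matrix([100.0], [50.0])
        out = differential_metabolites(X, groups)
        assert bool(out["differential"].iloc[0])

    def test_small_relative_difference_never_flagged(self):
        X, groups = self._matrix([12.0], [11.5], seed=1)
        X.iloc[:, 0] = np.where(groups == "a", 12.0, 11.5)  # zero-noise extreme
        out = differential_metabolites(X, groups)
        assert not bool(out["differential"].iloc[0])
        assert not bool(out["passes_magnitude"].iloc[0])

    def test_production_floor_excludes_low_producers(self):
        X, groups = self._matrix([8.0], [2.0], seed=2)
        out = differential_metabolites(X, groups)
        assert not bool(out["differential"].iloc[0])

    def test_all_zero_metabolite_reported_untested(self):
        X, groups = self._matrix([50.0], [100.0], seed=3)
        X["dead"] = 0.0
        out = differential_metabolites(X, groups)
        assert not bool(out.loc["dead", "tested"])
        assert np.isnan(out.loc["dead", "p"])

    def test_q_dominates_p(self):
        X, groups = self._matrix([50.0, 20.0, 30.0], [60.0, 20.0, 15.0], seed=4)
        out = differential_metabolites(X, groups)
        tested = out[out["tested"]]
        assert (tested["q"] >= tested["p"] - 1e-12).all()


class TestClusterSelectionAndAssociation:
    def _result(self, counts):
        frame = pd.DataFrame(counts, columns=["gouty", "healthy"])
        assignments = []
        for cluster, row in frame.iterrows():
            assignments += [cluster] * int(row.sum())
        idx = [f"s{i}" for i in range(len(assignments))]
        return ClusterResult(
            assignments=pd.Series(assignments, index=idx), k=len(frame),
            centroids=np.empty((0,)), inertia=0.0, phenotype_counts=frame,
        )

    def test_study_design_counts_select_extreme_clusters(self):
        result = self._result([[22, 4], [11, 33], [6, 2]])
        high, low = select_high_low_clusters(result, min_size=10)
        assert (high, low) == (0, 1)  # the 8-sample cluster is excluded

    def test_association_reproduces_worked_tables(self):
        result = self._result([[22, 4], [11, 33], [6, 2]])
        assoc = cluster_phenotype_association(result, 0, 1)
        assert assoc.p_value < 1e-5
        assoc_small = cluster_phenotype_association(result, 2, 1)
        # equivalent to the healthy-oriented table [[33,11],[2,6]]
        assert assoc_small.p_value == pytest.approx(0.011, abs=5e-4)

    def test_too_few_large_clusters_rejected(self):
        result = self._result([[22, 4], [3, 2]])
        with pytest.raises(ValueError):
            select_high_low_clusters(result, min_size=10)


class TestCompareDiets:
    def _nmpc(self, seed=0, n=20, mets=6):
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(n)]
        X = pd.DataFrame(
            rng.uniform(5, 50, size=(n, mets)), index=idx,
            columns=[f"m{i}" for i in range(mets)],
        )
        X.iloc[: n // 2] += 40.0  # two separated capability groups
        return X

    def test_identical_matrices_agree_perfectly(self):
        X = self._nmpc()
        c = kmeans_cluster(X, 2, replicates=10, seed=0)
        comparison = compare_diets({"EUD": X, "HPD": X}, {"EUD": c, "HPD": c})
        assert comparison.agreement[("EUD", "HPD")] == 1.0
        for screen in comparison.screens.values():
            assert not screen["differential"].any()

    def test_small_noise_preserves_memberships(self):
        X = self._nmpc(seed=1)
        rng = np.random.default_rng(2)
        Y = X + rng.normal(0, 0.1, size=X.shape)
        ca = kmeans_cluster(X, 2, replicates=10, seed=0)
        cb = kmeans_cluster(Y, 2, replicates=10, seed=0)
        comparison = compare_diets({"EUD": X, "HPD": Y}, {"EUD": ca, "HPD": cb})
        assert comparison.agreement[("EUD", "HPD")] == 1.0

    def test_shifted_metabolite_flagged_between_matched_clusters(self):
        X = self._nmpc(seed=3, n=30)
        Y = X.copy()
        Y["m0"] = Y["m0"] * 3.0  # a fiber-product style diet shift
        ca = kmeans_cluster(X, 2, replicates=10, seed=0)
        cb = kmeans_cluster(Y, 2, replicates=10, seed=0)
        comparison = compare_diets({"EUD": X, "HFD": Y}, {"EUD": ca, "HFD": cb})
        for screen in comparison.screens.values():
            assert bool(screen.loc["m0", "differential"])

    def test_mismatched_sample_sets_rejected(self):
        X = self._nmpc()
        c = kmeans_cluster(X, 2, replicates=10, seed=0)
        with pytest.raises(ValueError):
            compare_diets({"EUD": X, "HPD": X.iloc[:-1]}, {"EUD": c, "HPD": c})


def test_co_clustering_agreement_counts_pairs():
    a = pd.Series([0, 0, 1, 1], index=list("wxyz"))
    b = pd.Series([1, 1, 0, 0], index=list("wxyz"))  # relabeled, same partition
    assert co_clustering_agreement(a, b) == 1.0
    c = pd.Series([0, 1, 0, 1], index=list("wxyz"))
    assert co_clustering_agreement(a, c) == pytest.approx(2 / 6)
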