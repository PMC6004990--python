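"""Subtype discovery: distances, UPGMA, cophenetic QC, tree cutting."""
import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import squareform
from sklearn.base import clone
from sklearn.metrics import adjusted_rand_score

from copdsubtype import cluster as cl
from copdsubtype.preprocess import subset_to_candidates, zscore_rows

from _oracles import (
    cophenetic_from_merges,
    naive_upgma,
    pairwise_correlation_distance,
    pearson,
)


def _random_dist(n, seed):
    rng = np.random.default_rng(seed)
    points = rng.normal(size=(n, 4))
    D = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    ids = [f"S{i}" for i in range(n)]
    return pd.DataFrame(D, index=ids, columns=ids)


class TestComputeDistance:
    def test_identical_columns_zero(self):
        col = np.arange(5.0)
        matrix = pd.DataFrame({"A": col, "B": col})
        for metric in ("correlation", "euclidean"):
            d = cl.compute_distance(matrix, metric)
            assert d.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_columns(self):
        matrix = pd.DataFrame({"A": [1.0, 2, 3], "B": [3.0, 2, 1]})
        d = cl.compute_distance(matrix, "correlation")
        assert d.loc["A", "B"] == pytest.approx(2.0)

    def test_matches_double_loop_oracle(self, small_expression):
        d = cl.compute_distance(small_expression, "correlation")
        oracle = pairwise_correlation_distance(small_expression.to_numpy().T)
        assert np.allclose(d.to_numpy(), oracle, atol=1e-10)

    def test_zero_variance_sample_named(self):
        matrix = pd.DataFrame({"A": [1.0, 2, 3], "BAD": [2.0, 2, 2]})
        with pytest.raises(ValueError, match="BAD"):
            cl.compute_distance(matrix, "correlation")

    def test_unknown_metric(self, small_expression):
        with pytest.raises(ValueError, match="metric"):
            cl.compute_distance(small_expression, "cosine")


class TestAverageLinkage:
    def test_three_point_forced_merges(self):
        ids = ["A", "B", "C"]
        D = pd.DataFrame(
            [[0, 1, 4], [1, 0, 4], [4, 4, 0]], index=ids, columns=ids, dtype=float
        )
        tree = cl.average_linkage_tree(D)
        assert tree.linkage[0, 2] == pytest.approx(1.0)
        assert tree.linkage[1, 2] == pytest.approx(4.0)
        assert {int(tree.linkage[0, 0]), int(tree.linkage[0, 1])} == {0, 1}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_merge_heights_match_naive_oracle(self, seed):
        D = _random_dist(8, seed)
        tree = cl.average_linkage_tree(D)
        heights, _ = naive_upgma(D.to_numpy())
        assert np.allclose(np.sort(tree.linkage[:, 2]), np.sort(heights), atol=1e-10)

    def test_duplicate_points_merge_at_zero(self):
        ids = ["A", "B", "C"]
        D = pd.DataFrame([[0, 0, 2], [0, 0, 2], [2, 2, 0]], index=ids, columns=ids, dtype=float)
        tree = cl.average_linkage_tree(D)
        assert tree.linkage[0, 2] == pytest.approx(0.0)

    def test_single_sample_errors(self):
        D = pd.DataFrame([[0.0]], index=["A"], columns=["A"])
        with pytest.raises(ValueError, match="at least 2"):
            cl.average_linkage_tree(D)


class TestCophenetic:
    def test_ultrametric_recovers_one(self):
        # distances already tree-consistent: two tight pairs, far apart
        ids = ["A", "B", "C", "D"]
        D = pd.DataFrame(
            [[0, 1, 5, 5], [1, 0, 5, 5], [5, 5, 0, 2], [5, 5, 2, 0]],
            index=ids, columns=ids, dtype=float,
        )
        tree = cl.average_linkage_tree(D)
        assert cl.cophenetic_coefficient(tree, D) == pytest.approx(1.0, abs=1e-9)

    def test_matches_double_loop_oracle(self):
        D = _random_dist(10, 5)
        tree = cl.average_linkage_tree(D)
        heights, members = naive_upgma(D.to_numpy())
        C = cophenetic_from_merges(10, heights, members)
        iu = np.triu_indices(10, 1)
        expected = pearson(D.to_numpy()[iu], C[iu])
        assert cl.cophenetic_coefficient(tree, D) == pytest.approx(expected, abs=1e-10)

    def test_two_samples_error(self):
        D = pd.DataFrame([[0, 1], [1, 0]], index=["A", "B"], columns=["A", "B"], dtype=float)
        tree = cl.average_linkage_tree(D)
        with pytest.raises(ValueError, match="fewer than 3"):
            cl.cophenetic_coefficient(tree, D)

    def test_cophenetic_distances_are_ultrametric(self):
        D = _random_dist(9, 8)
        tree = cl.average_linkage_tree(D)
        C = cl.cophenetic_distances(tree).to_numpy()
        n = C.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert C[i, k] <= max(C[i, j], C[j, k]) + 1e-12


class TestCutToSubtypes:
    def test_k_equals_n_gives_singletons(self):
        D = _random_dist(6, 2)
        tree = cl.average_linkage_tree(D)
        assignment = cl.cut_to_subtypes(tree, 6)
        assert assignment.counts().tolist() == [1] * 6

    def test_k_out_of_range(self):
        D = _random_dist(5, 2)
        tree = cl.average_linkage_tree(D)
        for k in (1, 6):
            with pytest.raises(ValueError, match="k must lie"):
                cl.cut_to_subtypes(tree, k)

    def test_labels_numbered_by_decreasing_size(self):
        D = _random_dist(12, 4)
        tree = cl.average_linkage_tree(D)
        assignment = cl.cut_to_subtypes(tree, 3)
        sizes = [int((assignment.labels == c).sum()) for c in (1, 2, 3)]
        assert sizes == sorted(sizes, reverse=True)

    def test_cut_nesting(self):
        """Merging two clusters of the k-cut reproduces the (k-1)-cut."""
        D = _random_dist(15, 9)
        tree = cl.average_linkage_tree(D)
        fine = cl.cut_to_subtypes(tree, 4).labels
        coarse = cl.cut_to_subtypes(tree, 3).labels
        merged_pairs = set()
        for c in coarse.unique():
            merged_pairs.add(frozenset(fine[coarse == c].unique()))
        # exactly one coarse cluster unites two fine clusters; others map 1:1
        sizes = sorted(len(p) for p in merged_pairs)
        assert sizes == [1, 1, 2]

    def test_permutation_equivariance(self, high_sep_cohort):
        expr, _, truth = high_sep_cohort
        z, _ = zscore_rows(expr)
        cand = subset_to_candidates(z, truth.candidate_genes)
        rng = np.random.default_rng(0)
        perm = rng.permutation(cand.shape[1])
        shuffled = cand.iloc[:, perm]

        def labels_of(matrix):
            dist = cl.compute_distance(matrix)
            return cl.cut_to_subtypes(cl.average_linkage_tree(dist), 3).labels

        a, b = labels_of(cand), labels_of(shuffled)
        assert adjusted_rand_score(a.loc[b.index], b) == pytest.approx(1.0)


class TestHierarchicalSubtyper:
    def test_recovers_planted_labels(self, high_sep_cohort):
        expr, _, truth = high_sep_cohort
        z, _ = zscore_rows(expr)
        cand = subset_to_candidates(z, truth.candidate_genes)
        est = cl.HierarchicalSubtyper(n_subtypes=3).fit(cand.T)
        assert adjusted_rand_score(truth.labels.to_numpy(), est.labels_) >= 0.9
        assert 0 <= est.cophenetic_coefficient_ <= 1

    def test_sklearn_contract(self):
        est = cl.HierarchicalSubtyper(n_subtypes=4, metric="euclidean")
        assert clone(est).get_params() == est.get_params()

    def test_newick_export_contains_all_leaves(self, small_expression):
        dist = cl.compute_distance(small_expression)
        tree = cl.average_linkage_tree(dist)
        newick = cl.to_newick(tree)
        assert newick.endswith(";")
        for leaf in small_expression.columns:
            assert leaf in newick
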