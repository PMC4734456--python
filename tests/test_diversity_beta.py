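"""UniFrac, Gower centering, and PCoA against independent oracles.

The primary oracle is a brute-force edge classifier written directly on the
dendropy tree (explicit per-edge leaf sets); scikit-bio provides a second,
fully external implementation for cross-checking.
"""

import dendropy
import numpy as np
import pandas as pd
import pytest

from microdemog.data_model import CountTable, DistanceMatrix, PhyloTree, ValidationError
from microdemog.diversity_beta import (
    gower_center,
    pairwise_distances,
    pcoa,
    unweighted_unifrac,
    weighted_unifrac,
)
from microdemog.synthetic_data import simulate_tree


def brute_force_unifrac(newick, counts_a, counts_b, weighted):
    """Independent UniFrac by explicit enumeration of every edge's leaf set."""
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tot_a = sum(counts_a.values())
    tot_b = sum(counts_b.values())
    unique = union = num = den = 0.0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        bl = node.edge.length or 0.0
        mass_a = sum(counts_a.get(l, 0) for l in leaves)
        mass_b = sum(counts_b.get(l, 0) for l in leaves)
        in_a, in_b = mass_a > 0, mass_b > 0
        if in_a or in_b:
            union += bl
            if in_a != in_b:
                unique += bl
        pa, pb = mass_a / tot_a, mass_b / tot_b
        num += bl * abs(pa - pb)
        den += bl * (pa + pb)
    if weighted:
        return num / den if den > 0 else 0.0
    return unique / union if union > 0 else 0.0


def skbio_unifrac(newick, a, b, otu_ids, weighted):
    import io

    from skbio import TreeNode
    from skbio.diversity import beta_diversity

    tree = TreeNode.read(io.StringIO(newick), convert_underscores=False)
    metric = "weighted_unifrac" if weighted else "unweighted_unifrac"
    dm = beta_diversity(metric, np.vstack([a, b]), ids=["x", "y"],
                        taxa=list(otu_ids), tree=tree,
                        **({"normalized": True} if weighted else {}))
    return dm["x", "y"]


FOUR_TIP = "((A:1,B:1):1,(C:1,D:1):1);"


class TestUniFracPairs:
    def test_identical_presence_is_zero(self):
        t = PhyloTree.from_newick(FOUR_TIP)
        ids = ["A", "B", "C", "D"]
        assert unweighted_unifrac([1, 2, 0, 0], [5, 1, 0, 0], t, ids) == 0.0

    def test_two_tip_disjoint_is_one(self):
        t = PhyloTree.from_newick("(A:1.5,B:0.5);")
        assert unweighted_unifrac([3, 0], [0, 9], t, ["A", "B"]) == 1.0
        assert weighted_unifrac([3, 0], [0, 9], t, ["A", "B"]) == 1.0

    def test_weighted_identical_profiles_zero(self):
        t = PhyloTree.from_newick(FOUR_TIP)
        ids = ["A", "B", "C", "D"]
        assert weighted_unifrac([2, 4, 2, 0], [1, 2, 1, 0], t, ids) == pytest.approx(0.0)

    def test_four_tip_worked_example_matches_brute_force(self):
        ids = ["A", "B", "C", "D"]
        a = {"A": 1, "B": 1, "C": 0, "D": 0}
        b = {"A": 1, "B": 0, "C": 1, "D": 0}
        t = PhyloTree.from_newick(FOUR_TIP)
        got = unweighted_unifrac([1, 1, 0, 0], [1, 0, 1, 0], t, ids)
        assert got == pytest.approx(
            brute_force_unifrac(FOUR_TIP, a, b, weighted=False), abs=1e-12)
        # hand count: unique = B(1), C(1), and the CD internal edge (1);
        # union = A, B, C edges + both internals = 5 (D's edge in neither)
        assert got == pytest.approx(3.0 / 5.0)

    def test_empty_community_rejected(self):
        t = PhyloTree.from_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            unweighted_unifrac([0, 0], [1, 0], t, ["A", "B"])

    @pytest.mark.parametrize("weighted", [False, True])
    def test_random_trees_match_brute_force(self, weighted):
        rng = np.random.default_rng(42)
        for rep in range(50):
            n_tips = int(rng.integers(3, 9))
            tree = simulate_tree(n_tips, seed=1000 + rep)
            ids = tree.tip_labels
            a = rng.integers(0, 5, n_tips)
            b = rng.integers(0, 5, n_tips)
            if a.sum() == 0:
                a[0] = 1
            if b.sum() == 0:
                b[-1] = 1
            fn = weighted_unifrac if weighted else unweighted_unifrac
            got = fn(a, b, tree, ids)
            want = brute_force_unifrac(tree.to_newick(), dict(zip(ids, a)),
                                       dict(zip(ids, b)), weighted)
            assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_cross_check_against_scikit_bio(self, weighted):
        rng = np.random.default_rng(7)
        for rep in range(10):
            tree = simulate_tree(6, seed=2000 + rep)
            ids = tree.tip_labels
            a = rng.integers(0, 6, 6)
            b = rng.integers(0, 6, 6)
            a[0] = max(a[0], 1)
            b[-1] = max(b[-1], 1)
            fn = weighted_unifrac if weighted else unweighted_unifrac
            got = fn(a, b, tree, ids)
            want = skbio_unifrac(tree.to_newick(), a, b, ids, weighted)
            assert got == pytest.approx(want, abs=1e-10)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        tree = simulate_tree(10, seed=77)
        ids = tree.tip_labels
        for _ in range(200):
            a = rng.integers(0, 4, 10)
            b = rng.integers(0, 4, 10)
            a[0] = max(a[0], 1)
            b[-1] = max(b[-1], 1)
            assert unweighted_unifrac(a, b, tree, ids) == pytest.approx(
                unweighted_unifrac(b, a, tree, ids), abs=1e-14)
            assert weighted_unifrac(a, b, tree, ids) == pytest.approx(
                weighted_unifrac(b, a, tree, ids), abs=1e-14)

    def test_unweighted_invariant_to_count_rescaling(self):
        tree = simulate_tree(8, seed=5)
        ids = tree.tip_labels
        a = np.array([3, 0, 1, 0, 2, 0, 0, 4])
        b = np.array([0, 1, 1, 2, 0, 0, 3, 0])
        assert unweighted_unifrac(a * 7, b, tree, ids) == pytest.approx(
            unweighted_unifrac(a, b, tree, ids), abs=1e-14)


class TestPairwiseDistances:
    def _table(self, rows, otus):
        df = pd.DataFrame(rows, index=[f"S{i}" for i in range(len(rows))],
                          columns=otus)
        return CountTable(df)

    def test_three_samples_symmetric_zero_diagonal(self):
        tree = PhyloTree.from_newick(FOUR_TIP)
        t = self._table([[5, 5, 0, 0], [0, 5, 5, 0], [2, 2, 3, 3]],
                        ["A", "B", "C", "D"])
        D = pairwise_distances(t, tree, metric="unweighted", seed=1)
        assert D.values.shape == (3, 3)
        np.testing.assert_allclose(D.values, D.values.T)
        assert np.allclose(np.diag(D.values), 0)

    def test_duplicate_rows_have_zero_distance(self):
        tree = PhyloTree.from_newick(FOUR_TIP)
        t = self._table([[40, 60, 5, 0], [40, 60, 5, 0], [0, 1, 50, 50]],
                        ["A", "B", "C", "D"])
        for metric in ("unweighted", "weighted"):
            D = pairwise_distances(t, tree, metric=metric, rarefy_depth=50, seed=9)
            assert D.values[0, 1] == pytest.approx(0.0, abs=1e-14)

    def test_membership_vs_abundance_sensitivity(self):
        # same presence profile, different abundances
        tree = PhyloTree.from_newick("(A:1,B:1);")
        t = self._table([[50, 50], [80, 20]], ["A", "B"])
        Du = pairwise_distances(t, tree, "unweighted", rarefy_depth=100, seed=0)
        Dw = pairwise_distances(t, tree, "weighted", rarefy_depth=100, seed=0)
        assert Du.values[0, 1] == pytest.approx(0.0)
        assert Dw.values[0, 1] > 0.05

    def test_missing_otus_hard_error_and_prune_flag(self):
        tree = PhyloTree.from_newick("(A:1,B:1);")
        t = self._table([[5, 5, 2], [1, 9, 3]], ["A", "B", "Z"])
        with pytest.raises(ValidationError, match="absent from tree"):
            pairwise_distances(t, tree, "unweighted", rarefy_depth=5, seed=0)
        D = pairwise_distances(t, tree, "unweighted", rarefy_depth=5, seed=0,
                               prune_missing=True)
        assert D.n == 2

    def test_matches_pair_function_on_cohort(self, small_cohort):
        table, tree, _, _ = small_cohort
        depth = int(table.depths().min())
        D = pairwise_distances(table, tree, "weighted", rarefy_depth=depth, seed=4)
        from microdemog.diversity_alpha import rarefy

        rt = rarefy(table, depth, seed=4)
        i, j = 0, 7
        want = weighted_unifrac(rt.counts[i], rt.counts[j], tree, rt.otu_ids)
        assert D.values[i, j] == pytest.approx(want, abs=1e-12)


class TestGower:
    def test_zero_distances_give_zero_matrix(self):
        D = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        assert np.allclose(gower_center(D).values, 0)

    def test_two_point_hand_computation(self):
        D = DistanceMatrix(["a", "b"], np.array([[0.0, 2.0], [2.0, 0.0]]))
        G = gower_center(D).values
        np.testing.assert_allclose(G, [[1, -1], [-1, 1]], atol=1e-12)
        assert np.trace(G) == pytest.approx(2.0)

    def test_rows_sum_to_zero_and_trace_identity(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(7, 3))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pts))
        D = DistanceMatrix([f"s{i}" for i in range(7)], d)
        G = gower_center(D).values
        np.testing.assert_allclose(G.sum(axis=1), 0, atol=1e-10)
        assert np.trace(G) == pytest.approx((d[np.triu_indices(7, 1)] ** 2).sum() / 7)


class TestPCoA:
    def test_collinear_points_one_axis(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        d = np.abs(x[:, None] - x[None, :])
        D = DistanceMatrix(list("abcd"), d)
        ord_ = pcoa(D, k=3)
        assert ord_.explained[0] == pytest.approx(1.0, abs=1e-10)
        rec = np.abs(ord_.coordinates[:, 0][:, None] - ord_.coordinates[:, 0][None, :])
        np.testing.assert_allclose(rec, d, atol=1e-8)

    def test_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(9, 2))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pts))
        D = DistanceMatrix([f"s{i}" for i in range(9)], d)
        ord_ = pcoa(D, k=2)
        rec = squareform(pdist(ord_.coordinates))
        np.testing.assert_allclose(rec, d, atol=1e-8)

    def test_zero_matrix_empty_ordination(self):
        D = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        ord_ = pcoa(D, k=2)
        assert ord_.coordinates.shape[1] == 0

    def test_explained_fractions_non_increasing(self, small_cohort):
        table, tree, _, _ = small_cohort
        D = pairwise_distances(table, tree, "unweighted", seed=1)
        ord_ = pcoa(D, k=5)
        assert all(b <= a + 1e-12 for a, b in zip(ord_.explained, ord_.explained[1:]))
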