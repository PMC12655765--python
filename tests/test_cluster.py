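"""Ward.D2 clustering, inertia-based k selection, cophenetic validation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from pgxnet import cluster as cl


def block_similarity(block_sizes, within=1.0, between=0.0):
    ids, truth = [], []
    for b, size in enumerate(block_sizes):
        for i in range(size):
            ids.append(f"b{b}_{i}")
            truth.append(b)
    n = len(ids)
    s = np.full((n, n), between)
    truth_arr = np.array(truth)
    for b in range(len(block_sizes)):
        mask = truth_arr == b
        s[np.ix_(mask, mask)] = within
    np.fill_diagonal(s, 1.0)
    return pd.DataFrame(s, index=ids, columns=ids), truth


class TestToDistance:
    def test_complement_and_diagonal(self):
        S, _ = block_similarity([2, 2], within=0.725)
        D = cl.to_distance(S)
        assert np.allclose(np.diag(D.values), 0.0)
        assert D.iloc[0, 2] == pytest.approx(1.0)
        assert D.iloc[0, 1] == pytest.approx(0.275)

    def test_asymmetric_raises(self):
        S = pd.DataFrame([[1.0, 0.2], [0.4, 1.0]],
                         index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="symmetric"):
            cl.to_distance(S)


class TestWardCluster:
    def test_two_leaves_merge_at_their_distance(self):
        D = pd.DataFrame([[0.0, 0.7], [0.7, 0.0]],
                         index=["a", "b"], columns=["a", "b"])
        tree = cl.ward_cluster(D)
        assert tree.linkage[0, 2] == pytest.approx(0.7)

    def test_well_separated_pairs_merge_first(self):
        # two tight pairs far apart: first merges join the pairs
        ids = ["a1", "a2", "b1", "b2"]
        D = pd.DataFrame(np.array([
            [0.0, 0.1, 5.0, 5.0],
            [0.1, 0.0, 5.0, 5.0],
            [5.0, 5.0, 0.0, 0.1],
            [5.0, 5.0, 0.1, 0.0],
        ]), index=ids, columns=ids)
        tree = cl.ward_cluster(D)
        first_two = {frozenset(map(int, row[:2])) for row in tree.linkage[:2]}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    def test_block_matrix_recovers_blocks(self):
        S, truth = block_similarity([3, 4, 3])
        tree = cl.ward_cluster(cl.to_distance(S))
        part = cl.cut_tree(tree, 3)
        assert adjusted_rand_score(truth, part.to_numpy()) == 1.0

    def test_nan_raises(self):
        D = pd.DataFrame([[0.0, np.nan], [np.nan, 0.0]],
                         index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="NaN"):
            cl.ward_cluster(D)


class TestSelectK:
    def test_three_zero_distance_blocks(self):
        S, _ = block_similarity([3, 3, 3])
        tree = cl.ward_cluster(cl.to_distance(S))
        assert cl.select_k_by_inertia(tree, 2, 8) == 3

    def test_five_planted_families(self):
        S, _ = block_similarity([4, 3, 5, 4, 3])
        tree = cl.ward_cluster(cl.to_distance(S))
        assert cl.select_k_by_inertia(tree, 2, 15) == 5

    def test_two_leaves_forced(self):
        D = pd.DataFrame([[0.0, 0.5], [0.5, 0.0]],
                         index=["a", "b"], columns=["a", "b"])
        assert cl.select_k_by_inertia(cl.ward_cluster(D)) == 2

    def test_degenerate_tree_warns_and_returns_k_min(self):
        ids = list("abcd")
        D = pd.DataFrame(1.0 - np.eye(4), index=ids, columns=ids)
        tree = cl.ward_cluster(D)
        if np.allclose(tree.linkage[:, 2], tree.linkage[0, 2]):
            with pytest.warns(UserWarning, match="degenerate"):
                assert cl.select_k_by_inertia(tree, 2, 3) == 2


class TestCutTree:
    def test_extremes(self):
        S, _ = block_similarity([2, 3])
        tree = cl.ward_cluster(cl.to_distance(S))
        assert cl.cut_tree(tree, 1).nunique() == 1
        assert cl.cut_tree(tree, 5).nunique() == 5
        with pytest.raises(ValueError):
            cl.cut_tree(tree, 6)

    def test_labels_numbered_by_first_appearance(self):
        S, _ = block_similarity([2, 2, 2])
        tree = cl.ward_cluster(cl.to_distance(S))
        part = cl.cut_tree(tree, 3)
        assert part.iloc[0] == 1
        assert list(dict.fromkeys(part)) == [1, 2, 3]

    def test_permutation_changes_only_labels(self):
        S, truth = block_similarity([3, 4, 3])
        perm = np.random.default_rng(1).permutation(len(S))
        S2 = S.iloc[perm, perm]
        p1 = cl.cut_tree(cl.ward_cluster(cl.to_distance(S)), 3)
        p2 = cl.cut_tree(cl.ward_cluster(cl.to_distance(S2)), 3)
        assert adjusted_rand_score(p1.loc[S.index], p2.loc[S.index]) == 1.0


class TestCophenetic:
    def test_ultrametric_distance_is_perfectly_preserved(self):
        # distances generated from a tree: d(a,b)=0.2, d(*,c)=0.8
        ids = ["a", "b", "c"]
        D = pd.DataFrame([[0.0, 0.2, 0.8], [0.2, 0.0, 0.8], [0.8, 0.8, 0.0]],
                         index=ids, columns=ids)
        tree = cl.ward_cluster(D, linkage_name="average")
        assert cl.cophenetic_correlation(tree, D) == pytest.approx(1.0)

    def test_two_leaves_undefined(self):
        D = pd.DataFrame([[0.0, 0.5], [0.5, 0.0]],
                         index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            cl.cophenetic_correlation(cl.ward_cluster(D), D)

    def test_matches_brute_force_from_merge_heights(self):
        rng = np.random.default_rng(3)
        n = 10
        pts = rng.standard_normal((n, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"x{i}" for i in range(n)]
        Ddf = pd.DataFrame(D, index=ids, columns=ids)
        tree = cl.ward_cluster(Ddf)

        # independent cophenetic matrix: lowest common merge height per pair
        members = {i: {i} for i in range(n)}
        coph = np.zeros((n, n))
        for m, row in enumerate(tree.linkage):
            left, right, h = int(row[0]), int(row[1]), row[2]
            for i in members[left]:
                for j in members[right]:
                    coph[i, j] = coph[j, i] = h
            members[n + m] = members.pop(left) | members.pop(right)
        iu = np.triu_indices(n, 1)
        expected = np.corrcoef(D[iu], coph[iu])[0, 1]
        assert cl.cophenetic_correlation(tree, Ddf) == pytest.approx(expected, abs=1e-12)
        assert -1.0 <= expected <= 1.0


class TestNewickAndOrdering:
    def test_two_leaves(self):
        D = pd.DataFrame([[0.0, 0.7], [0.7, 0.0]],
                         index=["a", "b"], columns=["a", "b"])
        assert cl.to_newick(cl.ward_cluster(D)) == "(a:0.7,b:0.7);"

    def test_four_leaf_hand_tree(self):
        ids = ["a", "b", "c", "d"]
        D = pd.DataFrame(np.array([
            [0.0, 0.2, 1.0, 1.0],
            [0.2, 0.0, 1.0, 1.0],
            [1.0, 1.0, 0.0, 0.4],
            [1.0, 1.0, 0.4, 0.0],
        ]), index=ids, columns=ids)
        tree = cl.ward_cluster(D, linkage_name="average")
        # merges: (a,b)@0.2, (c,d)@0.4, root@1.0; child length = parent - child height
        assert cl.to_newick(tree) == "((a:0.2,b:0.2):0.8,(c:0.4,d:0.4):0.6);"
        # leaf order in the newick matches the ordered-matrix header
        om = cl.ordered_matrix(D, tree)
        assert list(om.columns) == tree.leaf_order() == ["a", "b", "c", "d"]

    def test_newick_parses_with_dendropy(self):
        import dendropy
        S, _ = block_similarity([3, 3])
        tree = cl.ward_cluster(cl.to_distance(S))
        t = dendropy.Tree.get(data=cl.to_newick(tree), schema="newick",
                              preserve_underscores=True)
        assert {leaf.taxon.label for leaf in t.leaf_node_iter()} == set(S.index)
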