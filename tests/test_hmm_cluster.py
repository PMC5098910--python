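import math

import numpy as np
import pytest

from _oracles import brute_force_average_linkage
from idrscape.hmm_cluster import (
    Dendrogram,
    DissimilarityMatrix,
    ProbabilityMatrix,
    average_linkage,
    cluster_probabilities,
    read_probability_matrix,
    to_dissimilarity,
    to_newick,
)
from idrscape.synthetic_data import GeneratorSpec, gen_block_matrix


def random_dissimilarity(rng: np.random.Generator, n: int) -> DissimilarityMatrix:
    m = rng.uniform(0.1, 10.0, size=(n, n))
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    return DissimilarityMatrix([f"x{i}" for i in range(n)], m)


class TestToDissimilarity:
    def test_probability_one_is_zero_distance(self):
        P = ProbabilityMatrix(["a", "b"], [[1.0, 1.0], [1.0, 1.0]])
        assert to_dissimilarity(P).values[0, 1] == 0.0

    def test_probability_zero_hits_floor(self):
        P = ProbabilityMatrix(["a", "b"], [[1.0, 0.0], [0.0, 1.0]])
        D = to_dissimilarity(P)
        assert D.values[0, 1] == pytest.approx(-math.log(0.001), abs=1e-9)

    def test_asymmetric_entries_mean_symmetrized(self):
        P = ProbabilityMatrix(["a", "b"], [[1.0, 0.5], [0.25, 1.0]])
        D = to_dissimilarity(P)
        expected = 0.5 * (-math.log(0.5) - math.log(0.25))
        assert D.values[0, 1] == pytest.approx(expected, abs=1e-12)
        assert D.values[1, 0] == pytest.approx(expected, abs=1e-12)

    def test_zeros_only_mode_keeps_tiny_probabilities(self):
        P = ProbabilityMatrix(["a", "b"], [[1.0, 1e-6], [1e-6, 1.0]])
        all_mode = to_dissimilarity(P, floor_mode="all")
        zeros_mode = to_dissimilarity(P, floor_mode="zeros_only")
        assert all_mode.values[0, 1] == pytest.approx(-math.log(0.001))
        assert zeros_mode.values[0, 1] == pytest.approx(-math.log(1e-6))

    def test_monotone_after_flooring(self):
        rng = np.random.default_rng(1)
        p = np.sort(rng.uniform(0, 1, size=30))
        n = 30
        # build a symmetric matrix whose off-diagonal entries are the sorted p
        P = np.ones((2, 2))
        for i in range(n - 1):
            P = ProbabilityMatrix(["a", "b"], [[1.0, p[i]], [p[i], 1.0]])
            Q = ProbabilityMatrix(["a", "b"], [[1.0, p[i + 1]], [p[i + 1], 1.0]])
            assert to_dissimilarity(P).values[0, 1] >= \
                to_dissimilarity(Q).values[0, 1] - 1e-12

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            ProbabilityMatrix(["a", "b"], [[1.0, 0.5]])


class TestAverageLinkage:
    def test_two_leaves_single_merge(self):
        D = DissimilarityMatrix(["a", "b"], [[0.0, 2.0], [2.0, 0.0]])
        tree = average_linkage(D)
        assert tree.Z.shape == (1, 4)
        assert tree.heights[0] == pytest.approx(2.0)

    def test_four_leaf_hand_matrix_matches_brute_force(self):
        m = np.array([
            [0.0, 1.0, 6.0, 7.0],
            [1.0, 0.0, 5.0, 8.0],
            [6.0, 5.0, 0.0, 2.0],
            [7.0, 8.0, 2.0, 0.0],
        ])
        labels = ["a", "b", "c", "d"]
        tree = average_linkage(DissimilarityMatrix(labels, m))
        merges = tree.merge_members()
        oracle = brute_force_average_linkage(m, labels)
        assert [({l, r}, pytest.approx(h)) for l, r, h in oracle] == \
               [({l, r}, h) for l, r, h in merges]

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(99)
        for trial in range(100):
            n = int(rng.integers(2, 9))
            D = random_dissimilarity(rng, n)
            merges = average_linkage(D).merge_members()
            oracle = brute_force_average_linkage(D.values, D.labels)
            for (ol, orr, oh), (ml, mr, mh) in zip(oracle, merges):
                assert {ol, orr} == {ml, mr}
                assert mh == pytest.approx(oh, abs=1e-9)

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(50)
        tree = average_linkage(random_dissimilarity(rng, 12))
        assert (np.diff(tree.heights) >= -1e-12).all()

    def test_invariant_under_label_permutation(self):
        rng = np.random.default_rng(17)
        D = random_dissimilarity(rng, 7)
        perm = rng.permutation(7)
        Dp = DissimilarityMatrix([D.labels[i] for i in perm],
                                 D.values[np.ix_(perm, perm)])
        a = {frozenset(l | r): pytest.approx(h)
             for l, r, h in average_linkage(D).merge_members()}
        b = {frozenset(l | r): h
             for l, r, h in average_linkage(Dp).merge_members()}
        assert set(a) == set(b)
        for k in a:
            assert a[k] == b[k]

    def test_ultrametric_input_reproduced_by_cophenetic_distances(self):
        # constructed ultrametric: ((a,b):1, (c,d):2):5
        m = np.array([
            [0.0, 1.0, 5.0, 5.0],
            [1.0, 0.0, 5.0, 5.0],
            [5.0, 5.0, 0.0, 2.0],
            [5.0, 5.0, 2.0, 0.0],
        ])
        D = DissimilarityMatrix(["a", "b", "c", "d"], m)
        coph = average_linkage(D).cophenetic()
        np.testing.assert_allclose(coph.values, m, atol=1e-9)

    def test_planted_blocks_recovered_by_cut(self):
        P, blocks = gen_block_matrix(GeneratorSpec(seed=12, block_sizes=(5, 5)))
        tree = cluster_probabilities(P)
        cut = tree.cut(2.0)
        groups = {}
        for label, cl in cut.items():
            groups.setdefault(cl, set()).add(label)
        expected = {}
        for label, b in zip(P.labels, blocks):
            expected.setdefault(b, set()).add(label)
        assert set(map(frozenset, groups.values())) == \
               set(map(frozenset, expected.values()))

    def test_nan_rejected(self):
        m = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="NaN"):
            average_linkage(DissimilarityMatrix(["a", "b"], m))

    def test_single_item_rejected(self):
        with pytest.raises(ValueError):
            average_linkage(DissimilarityMatrix(["a"], [[0.0]]))


class TestNewick:
    def test_two_leaves(self):
        D = DissimilarityMatrix(["a", "b"], [[0.0, 2.0], [2.0, 0.0]])
        nwk = to_newick(average_linkage(D))
        assert nwk == "(a:2,b:2);"

    def test_round_trip_preserves_topology_and_heights(self):
        import skbio
        rng = np.random.default_rng(77)
        D = random_dissimilarity(rng, 9)
        tree = average_linkage(D)
        parsed = skbio.TreeNode.read([to_newick(tree)])
        assert {t.name for t in parsed.tips()} == set(D.labels)
        # leaf-to-root path length equals the root merge height for every leaf
        root_height = tree.heights[-1]
        for tip in parsed.tips():
            assert tip.distance(parsed.root()) == pytest.approx(
                root_height, rel=1e-4)

    def test_caterpillar_nesting_depth(self):
        m = np.array([
            [0.0, 1.0, 4.0, 9.0],
            [1.0, 0.0, 4.0, 9.0],
            [4.0, 4.0, 0.0, 9.0],
            [9.0, 9.0, 9.0, 0.0],
        ])
        nwk = to_newick(average_linkage(
            DissimilarityMatrix(["a", "b", "c", "d"], m)))
        depth = max_depth = 0
        for ch in nwk:
            depth += ch == "("
            max_depth = max(max_depth, depth)
            depth -= ch == ")"
        assert max_depth == 3


class TestMatrixIO:
    def test_tsv_round_trip_and_percent_autodetect(self, tmp_path):
        import pandas as pd
        labels = ["f1", "f2", "f3"]
        vals = np.array([[100.0, 50.0, 1.0],
                         [50.0, 100.0, 2.0],
                         [1.0, 2.0, 100.0]])
        p = tmp_path / "m.tsv"
        pd.DataFrame(vals, index=labels, columns=labels).to_csv(p, sep="\t")
        P = read_probability_matrix(p)
        assert P.labels == labels
        np.testing.assert_allclose(P.values, vals / 100.0)
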