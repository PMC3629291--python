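import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import cophenet as sp_cophenet, linkage as sp_linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from mitophen import cluster as cl
from mitophen.errors import UndefinedSimilarityError, ValidationError
from mitophen.phenodb import build_matrix


def random_distance_matrix(rng, n):
    cond = rng.uniform(0.05, 2.0, size=n * (n - 1) // 2)
    return cl.DistanceMatrix(labels=[f"L{i}" for i in range(n)], d=squareform(cond))


class TestSimilarity:
    def test_self_similarity_is_one(self, rng):
        x = rng.uniform(1, 100, size=10)
        assert cl.similarity(x, x) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert cl.similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_uncentered_hand_value(self):
        # (3*4 + 4*3) / sqrt(25 * 25) = 24/25
        assert cl.similarity([3, 4], [4, 3]) == pytest.approx(0.96)

    @pytest.mark.parametrize("metric", ["uncentered", "pearson", "spearman", "kendall"])
    def test_all_zero_vector_rejected(self, metric):
        with pytest.raises(UndefinedSimilarityError):
            cl.similarity([0.0, 0.0, 0.0], [1.0, 2.0, 3.0], metric)

    def test_absolute_variants(self):
        x, y = [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]
        r = cl.similarity(x, y, "pearson")
        assert r < 0
        assert cl.similarity(x, y, "absolute-pearson") == pytest.approx(abs(r))

    def test_distance_metrics_return_distances(self):
        assert cl.similarity([0.0, 3.0], [4.0, 0.0], "euclidean") == pytest.approx(5.0)
        assert cl.similarity([0.0, 3.0], [4.0, 0.0], "cityblock") == pytest.approx(7.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.1, max_value=100), min_size=2, max_size=8),
        st.floats(min_value=0.01, max_value=50),
        st.floats(min_value=0.01, max_value=50),
    )
    def test_uncentered_scale_invariance(self, xs, a, b):
        x = np.array(xs)
        y = x[::-1].copy()
        s0 = cl.similarity(x, y)
        s1 = cl.similarity(a * x, b * y)
        assert s1 == pytest.approx(s0, abs=1e-9)


class TestPairwiseDistances:
    def test_identical_rows_have_zero_distance(self):
        from mitophen.phenodb import DiseaseProfile

        m = build_matrix(
            [
                DiseaseProfile("a", "positive", {"x": 50.0, "y": 10.0}),
                DiseaseProfile("b", "negative", {"x": 50.0, "y": 10.0}),
            ]
        )
        dm = cl.pairwise_distances(m)
        assert dm.d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_binary_rows_distance_one(self):
        from mitophen.phenodb import DiseaseProfile

        m = build_matrix(
            [
                DiseaseProfile("a", "positive", {"x": 100.0}),
                DiseaseProfile("b", "negative", {"y": 100.0}),
            ]
        )
        assert cl.pairwise_distances(m).d[0, 1] == pytest.approx(1.0)

    def test_matches_elementwise_loop(self, rng):
        from conftest import random_profiles

        m = build_matrix(random_profiles(rng, n_diseases=4))
        dm = cl.pairwise_distances(m, "uncentered")
        for i, j in itertools.combinations(range(4), 2):
            x, y = m.values[i], m.values[j]
            expected = 1 - np.dot(x, y) / np.sqrt(np.dot(x, x) * np.dot(y, y))
            assert dm.d[i, j] == pytest.approx(max(expected, 0.0), abs=1e-9)


class TestLinkage:
    def test_two_leaves_single_merge(self):
        dm = cl.DistanceMatrix(["A", "B"], np.array([[0.0, 0.7], [0.7, 0.0]]))
        tree = cl.linkage(dm)
        assert tree.merges == [(0, 1, 0.7)]

    def test_three_leaf_average_oracle(self):
        # d(A,B)=1, d(A,C)=4, d(B,C)=5: merge (A,B) at 1, then C at (4+5)/2
        d = np.array([[0, 1, 4], [1, 0, 5], [4, 5, 0]], dtype=float)
        tree = cl.linkage(cl.DistanceMatrix(list("ABC"), d), "average")
        assert tree.merges == [(0, 1, 1.0), (2, 3, 4.5)]

    def test_three_leaf_single_oracle(self):
        d = np.array([[0, 1, 4], [1, 0, 5], [4, 5, 0]], dtype=float)
        tree = cl.linkage(cl.DistanceMatrix(list("ABC"), d), "single")
        assert tree.merges == [(0, 1, 1.0), (2, 3, 4.0)]

    @pytest.mark.parametrize("method", ["average", "single", "complete"])
    def test_cophenetic_matches_scipy(self, method, rng):
        for _ in range(20):
            n = int(rng.integers(3, 8))
            cond = rng.uniform(0.1, 2.0, size=n * (n - 1) // 2)
            dm = cl.DistanceMatrix([f"L{i}" for i in range(n)], squareform(cond))
            mine = cl.cophenetic_distances(cl.linkage(dm, method))
            ref = sp_cophenet(sp_linkage(cond, method=method))
            np.testing.assert_allclose(mine, ref, atol=1e-9)

    @pytest.mark.parametrize("method", ["average", "single", "complete"])
    def test_merge_heights_nondecreasing(self, method, rng):
        dm = random_distance_matrix(rng, 7)
        heights = [h for _a, _b, h in cl.linkage(dm, method).merges]
        assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))

    def test_single_leaf_rejected(self):
        with pytest.raises(ValidationError):
            cl.linkage(cl.DistanceMatrix(["A"], np.zeros((1, 1))))


class TestCophenetic:
    def test_ultrametric_input_gives_one(self):
        # distances already tree-consistent: (A,B) at 1, C at 3 from both
        d = np.array([[0, 1, 3], [1, 0, 3], [3, 3, 0]], dtype=float)
        dm = cl.DistanceMatrix(list("ABC"), d)
        assert cl.cophenetic_correlation(cl.linkage(dm), dm) == pytest.approx(1.0)

    def test_matches_pair_enumeration_oracle(self, rng):
        dm = random_distance_matrix(rng, 4)
        tree = cl.linkage(dm)
        n = 4
        orig, coph = [], []
        for i, j in itertools.combinations(range(n), 2):
            orig.append(dm.d[i, j])
            # lowest merge containing both leaves
            for a, b, h in tree.merges:
                la, lb = tree.node_leaves(a), tree.node_leaves(b)
                if (i in la and j in lb) or (j in la and i in lb):
                    coph.append(h)
                    break
        expected = pearsonr(orig, coph).statistic
        assert cl.cophenetic_correlation(tree, dm) == pytest.approx(expected, abs=1e-12)

    def test_two_leaves_rejected(self):
        dm = cl.DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        tree = cl.linkage(dm)
        with pytest.raises(ValidationError):
            cl.cophenetic_correlation(tree, dm)


class TestCutTree:
    def test_k_one_and_k_n(self, rng):
        dm = random_distance_matrix(rng, 5)
        tree = cl.linkage(dm)
        assert set(cl.cut_tree(tree, 1).values()) == {0}
        assert len(set(cl.cut_tree(tree, 5).values())) == 5

    def test_recovers_separated_groups(self, separable_matrix):
        ref_names = [
            d for d, g in zip(separable_matrix.diseases, separable_matrix.groups)
            if g != "test"
        ]
        ref = separable_matrix.subset_diseases(ref_names)
        tree = cl.linkage(cl.pairwise_distances(ref))
        cut = cl.cut_tree(tree, 2)
        clusters = {g: {cut[d] for d, g2 in zip(ref.diseases, ref.groups) if g2 == g}
                    for g in ("positive", "negative")}
        assert clusters["positive"] == {0}
        assert clusters["negative"] == {1}


class TestNewick:
    def test_two_leaf_shape(self):
        dm = cl.DistanceMatrix(["A", "B"], np.array([[0.0, 0.8], [0.8, 0.0]]))
        assert cl.to_newick(cl.linkage(dm)) == "(A:0.8,B:0.8);"

    def test_round_trip_preserves_cophenetic_structure(self, rng):
        dm = random_distance_matrix(rng, 5)
        tree = cl.linkage(dm)
        back = cl.from_newick(cl.to_newick(tree))

        def pair_heights(t):
            cd = cl.cophenetic_distances(t)
            pairs = itertools.combinations(t.leaves, 2)
            return {frozenset(p): h for p, h in zip(pairs, cd)}

        p1, p2 = pair_heights(tree), pair_heights(back)
        assert set(p1) == set(p2)
        for key in p1:
            assert p1[key] == pytest.approx(p2[key], abs=1e-9)

    def test_independent_parser_accepts_output(self, rng):
        import dendropy

        dm = random_distance_matrix(rng, 5)
        nwk = cl.to_newick(cl.linkage(dm))
        parsed = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
        assert {lf.taxon.label for lf in parsed.leaf_node_iter()} == set(dm.labels)

    def test_reserved_characters_are_quoted(self):
        dm = cl.DistanceMatrix(["a b", "c(d)"], np.array([[0.0, 0.5], [0.5, 0.0]]))
        nwk = cl.to_newick(cl.linkage(dm))
        back = cl.from_newick(nwk)
        assert set(back.leaves) == {"a b", "c(d)"}
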