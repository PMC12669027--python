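import math

import dendropy
import numpy as np
import pytest
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from hypothesis import given, settings, strategies as st

from crisprcensus.dendro import (DistanceMatrix, SimilarityMatrix, cut_at_depth,
                                 dendrogram_to_dendropy, graft, nj_merge,
                                 to_distance, upgma, REL_SCORE_EPS)
from crisprcensus.synth import simulate_similarity
from oracles import cophenetic_heights, upgma_heights_oracle


def random_similarity(rng, n):
    S = rng.uniform(5, 60, size=(n, n))
    S = (S + S.T) / 2
    for i in range(n):
        S[i, i] = rng.uniform(80, 120)
    return SimilarityMatrix([f"L{i}" for i in range(n)], S)


class TestToDistance:
    def test_self_comparison_is_zero(self):
        S = SimilarityMatrix(["A", "B"], np.array([[100.0, 100.0], [100.0, 120.0]]))
        d = to_distance(S)
        # cross score equals the smaller self-score: relative score 1, distance 0
        assert d.D[0, 1] == 0.0 and d.D[0, 0] == 0.0

    def test_negative_log_of_relative_score(self):
        S = SimilarityMatrix(["A", "B"], np.array([[100.0, 50.0], [50.0, 80.0]]))
        d = to_distance(S)
        assert d.D[0, 1] == pytest.approx(-math.log(50 / 80), abs=1e-4)
        assert d.D[0, 1] == pytest.approx(0.4700, abs=1e-4)

    def test_nonpositive_cross_score_hits_the_ceiling(self):
        S = SimilarityMatrix(["A", "B"], np.array([[100.0, 0.0], [0.0, 80.0]]))
        d = to_distance(S)
        assert d.D[0, 1] == pytest.approx(-math.log(REL_SCORE_EPS))

    def test_nonpositive_self_score_rejected(self):
        with pytest.raises(ValueError):
            SimilarityMatrix(["A"], np.array([[0.0]]))

    @given(st.floats(1.0, 100.0), st.floats(1.0, 100.0))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_in_cross_score(self, s1, s2):
        lo, hi = sorted((s1, s2))
        def dist(s_ab):
            S = SimilarityMatrix(["A", "B"],
                                 np.array([[110.0, s_ab], [s_ab, 105.0]]))
            return to_distance(S).D[0, 1]
        assert dist(hi) <= dist(lo) + 1e-12


class TestUpgma:
    def test_two_leaves(self):
        t = upgma(DistanceMatrix(["A", "B"], np.array([[0.0, 4.0], [4.0, 0.0]])))
        assert t.height == 2.0 and sorted(t.leaves()) == ["A", "B"]

    def test_three_leaf_hand_example(self):
        D = np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], float)
        t = upgma(DistanceMatrix(["A", "B", "C"], D))
        h = cophenetic_heights(t)
        assert h[frozenset(("A", "B"))] == 1.0
        assert h[frozenset(("A", "C"))] == h[frozenset(("B", "C"))] == 4.0

    def test_all_equal_distances_give_lexicographic_caterpillar(self):
        D = np.ones((4, 4)) - np.eye(4)
        t = upgma(DistanceMatrix(list("ABCD"), D))
        # first merge is (A,B); every later merge attaches the next label
        h = cophenetic_heights(t)
        assert h[frozenset(("A", "B"))] == 0.5
        assert h[frozenset(("A", "C"))] == h[frozenset(("B", "C"))] == 0.5
        assert t.height == 0.5

    def test_single_item_rejected(self):
        with pytest.raises(ValueError):
            upgma(DistanceMatrix(["A"], np.zeros((1, 1))))

    def test_matches_bruteforce_and_scipy_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            n = int(rng.integers(3, 9))
            sim = random_similarity(rng, n)
            dist = to_distance(sim)
            t = upgma(dist)
            got = cophenetic_heights(t)
            want = upgma_heights_oracle(dist.labels, dist.D)
            for pair, h in want.items():
                assert got[pair] == pytest.approx(h, rel=1e-9)
            # independent cross-check against scipy average linkage
            Z = sch.linkage(squareform(dist.D, checks=False), method="average")
            coph = squareform(sch.cophenet(Z))
            for i in range(n):
                for j in range(i + 1, n):
                    pair = frozenset((dist.labels[i], dist.labels[j]))
                    assert got[pair] == pytest.approx(coph[i, j] / 2, rel=1e-9)

    def test_heights_nondecreasing_towards_root(self):
        rng = np.random.default_rng(2)
        t = upgma(to_distance(random_similarity(rng, 8)))

        def walk(node):
            for c in node.children:
                assert c.height <= node.height + 1e-12
                walk(c)
        walk(t)


class TestCut:
    def make_tree(self):
        D = np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], float)
        return upgma(DistanceMatrix(["A", "B", "C"], D))

    def test_depth_zero_isolates_every_leaf(self):
        assert cut_at_depth(self.make_tree(), 0) == [["A"], ["B"], ["C"]]

    def test_depth_above_root_is_one_cluster(self):
        assert cut_at_depth(self.make_tree(), 10) == [["A", "B", "C"]]

    def test_intermediate_depth(self):
        assert cut_at_depth(self.make_tree(), 2) == [["A", "B"], ["C"]]

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            cut_at_depth(self.make_tree(), -1)

    def test_partitions_are_nested_in_depth(self):
        rng = np.random.default_rng(3)
        t = upgma(to_distance(random_similarity(rng, 8)))
        depths = sorted(rng.uniform(0, 2 * t.height, size=6))
        parts = [cut_at_depth(t, d) for d in depths]
        for finer, coarser in zip(parts, parts[1:]):
            for cluster in finer:
                assert any(set(cluster) <= set(c) for c in coarser)

    def test_planted_blocks_recovered_at_default_depth(self):
        sim, blocks = simulate_similarity(3, 4, seed=9)
        t = upgma(to_distance(sim))
        assert cut_at_depth(t, 0.8) == sorted(sorted(b) for b in blocks)


class TestGraft:
    def backbone(self):
        return dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")

    def test_leaf_count_conservation(self):
        sub = dendropy.Tree.get(data="(X:1,(Y:1,Z:1):1,W:2);", schema="newick")
        out = graft(self.backbone(), {"C": sub})
        leaves = sorted(l.taxon.label for l in out.leaf_node_iter())
        assert leaves == ["A", "B", "W", "X", "Y", "Z"]  # 2 unmapped + 4 grafted

    def test_empty_map_leaves_backbone_unchanged(self):
        out = graft(self.backbone(), {})
        assert sorted(l.taxon.label for l in out.leaf_node_iter()) == ["A", "B", "C"]

    def test_unknown_tip_rejected(self):
        with pytest.raises(KeyError):
            graft(self.backbone(), {"Z": self.backbone()})

    def test_duplicate_leaf_label_rejected(self):
        sub = dendropy.Tree.get(data="(A:1,X:1);", schema="newick")
        with pytest.raises(ValueError, match="duplicate"):
            graft(self.backbone(), {"C": sub})

    def test_dendrogram_newick_round_trip(self):
        D = np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], float)
        t = upgma(DistanceMatrix(["A", "B", "C"], D))
        tree = dendrogram_to_dendropy(t)
        depths = {l.taxon.label: l.distance_from_root()
                  for l in tree.leaf_node_iter()}
        assert all(d == pytest.approx(4.0) for d in depths.values())  # ultrametric


class TestMergeLoop:
    def sim(self, seed=0, n=4):
        rng = np.random.default_rng(seed)
        return random_similarity(rng, n)

    def test_single_cluster_returned_unchanged(self):
        s = SimilarityMatrix(["only"], np.array([[50.0]]))
        res = nj_merge(s, lambda c: (1.0, 0))
        assert list(res.clusters) == ["only"] and res.log == []

    def test_permissive_oracle_merges_everything(self):
        res = nj_merge(self.sim(), lambda c: (1.0, 0))
        assert len(res.clusters) == 1
        assert len([d for d in res.log if d.accepted]) == 3  # n-1 merges

    def test_retention_bound_is_strict(self):
        res = nj_merge(self.sim(), lambda c: (0.98, 0))
        assert all(not d.accepted for d in res.log)
        assert len(res.clusters) == 4

    def test_fp_bound_is_inclusive(self):
        accepted_at_10 = nj_merge(self.sim(), lambda c: (1.0, 10))
        rejected_at_11 = nj_merge(self.sim(), lambda c: (1.0, 11))
        assert len(accepted_at_10.clusters) == 1
        assert len(rejected_at_11.clusters) == 4

    def test_log_never_contains_an_invalid_accepted_merge(self):
        import zlib

        def adversary(candidate):
            # deterministic per candidate, spanning both sides of each bound
            h = zlib.crc32("|".join(candidate).encode()) % 100
            return (0.90 + h / 500.0, h % 15)

        for seed in range(10):
            res = nj_merge(self.sim(seed=seed, n=6), adversary)
            for d in res.log:
                if d.accepted:
                    assert d.retention > 0.98 and d.new_fp <= 10
                else:
                    assert d.retention <= 0.98 or d.new_fp > 10

    def test_terminates_and_is_order_invariant(self):
        s = self.sim(seed=5, n=5)
        perm = [3, 1, 4, 0, 2]
        s2 = SimilarityMatrix([s.labels[i] for i in perm],
                              s.S[np.ix_(perm, perm)])
        oracle = lambda c: (1.0, 0) if len(c) <= 2 else (0.5, 99)
        r1 = nj_merge(s, oracle)
        r2 = nj_merge(s2, oracle)
        assert sorted(map(sorted, r1.clusters.values())) == \
            sorted(map(sorted, r2.clusters.values()))
        assert len([d for d in r1.log if d.accepted]) <= len(s.labels) - 1
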