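"""Structural embeddings: degree sequences, DTW distance, layer recurrence."""

import itertools

import numpy as np
import pytest

from neurowalk.struc2vec import (
    build_layer_graphs,
    degree_sequence,
    sequence_distance,
    struc2vec_embed,
)
from conftest import graph_from_edges


def exhaustive_dtw(a, b):
    """Oracle: minimum alignment cost over all monotone warping paths."""
    def cost(x, y):
        x, y = max(x, 1), max(y, 1)
        return max(x, y) / min(x, y) - 1.0

    if not a and not b:
        return 0.0
    if not a or not b:
        seq = a or b
        return sum(cost(x, 1) for x in seq)

    best = [np.inf]

    def walk(i, j, acc):
        acc = acc + cost(a[i], b[j])
        if acc >= best[0]:
            return
        if i == len(a) - 1 and j == len(b) - 1:
            best[0] = acc
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ni, nj = i + di, j + dj
            if ni < len(a) and nj < len(b):
                walk(ni, nj, acc)

    walk(0, 0, 0.0)
    return best[0]


class TestDegreeSequence:
    def test_cycle_ring_symmetry(self, c6):
        for node in range(6):
            assert degree_sequence(c6, node, 1).R_k == [2, 2]

    def test_star_center_leaves(self, star4):
        assert degree_sequence(star4, 0, 1).R_k == [1, 1, 1, 1]
        assert degree_sequence(star4, 1, 1).R_k == [4]
        assert degree_sequence(star4, 1, 2).R_k == [1, 1, 1]

    def test_k0_is_own_degree(self, star4):
        assert degree_sequence(star4, 0, 0).R_k == [4]

    def test_matches_bfs_layering_oracle(self):
        rng = np.random.default_rng(5)
        a = (rng.random((10, 10)) < 0.3).astype(float)
        a = np.triu(a, 1)
        a = a + a.T
        g = graph_from_edges(10, [])
        g.adjacency = a
        deg = (a > 0).sum(axis=1)
        # independent BFS oracle
        for node in range(10):
            dist = {node: 0}
            frontier = [node]
            k = 0
            while frontier:
                k += 1
                nxt = []
                for u in frontier:
                    for v in np.nonzero(a[u] > 0)[0]:
                        if v not in dist:
                            dist[v] = k
                            nxt.append(v)
                frontier = nxt
            for kk in range(1, 4):
                expected = sorted(int(deg[v]) for v, dd in dist.items() if dd == kk)
                assert degree_sequence(g, node, kk).R_k == expected


class TestSequenceDistance:
    def test_identical_sequences_zero(self):
        assert sequence_distance([2, 3], [2, 3]) == 0.0

    def test_single_pair_cost(self):
        assert sequence_distance([2], [4]) == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = list(rng.integers(1, 8, rng.integers(1, 5)))
            b = list(rng.integers(1, 8, rng.integers(1, 5)))
            assert sequence_distance(a, b) == pytest.approx(sequence_distance(b, a))

    def test_matches_exhaustive_alignment_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            a = list(map(int, rng.integers(1, 9, 3)))
            b = list(map(int, rng.integers(1, 9, 4)))
            assert sequence_distance(a, b) == pytest.approx(exhaustive_dtw(a, b))

    def test_negative_degree_rejected(self):
        with pytest.raises(ValueError):
            sequence_distance([-1], [2])


class TestLayerGraphs:
    def test_vertex_transitive_cycle_all_zero(self, c6):
        layers = build_layer_graphs(c6, K=3)
        for w in layers.W:
            assert np.allclose(w, 0.0)

    def test_automorphic_star_leaves_zero(self, star4):
        layers = build_layer_graphs(star4, K=2)
        assert layers.W[-1][1, 2] == 0.0  # two leaves are automorphic

    def test_w0_zero_and_monotone(self, barbell):
        layers = build_layer_graphs(barbell, K=3)
        assert np.allclose(layers.W[0], 0.0)
        for wa, wb in zip(layers.W, layers.W[1:]):
            assert np.all(wb >= wa - 1e-12)
            assert np.allclose(wb, wb.T)
            assert np.all(np.diag(wb) == 0)

    def test_toy_graph_w2_matches_compositional_oracle(self):
        # 6-node graph: triangle 0-1-2 with pendant path 2-3-4 and leaf 5 on 0
        g = graph_from_edges(6, [(0, 1), (1, 2), (0, 2), (2, 3), (3, 4), (0, 5)])
        layers = build_layer_graphs(g, K=2)
        expected = np.zeros((6, 6))
        for i, j in itertools.combinations(range(6), 2):
            acc = 0.0
            for k in (1, 2):
                ra = degree_sequence(g, i, k).R_k
                rb = degree_sequence(g, j, k).R_k
                acc += exhaustive_dtw(ra, rb)
                if k == 2:
                    assert layers.W[2][i, j] == pytest.approx(acc)
                    expected[i, j] = expected[j, i] = acc
        assert np.allclose(layers.W[2], expected)


class TestStruc2VecEmbedding:
    def test_dimension_contract(self, barbell):
        emb = struc2vec_embed(barbell, d=64, K=2, walks_per_node=3, walk_length=10,
                              window=3, epochs=1, seed=0)
        assert emb.Z.shape == (11, 64)

    def test_cycle_symmetry_no_outlier_pairs(self, c6):
        # all C6 nodes are structurally identical: no pairwise embedding
        # distance should dominate, averaged over seeds
        ratios = []
        for seed in range(5):
            z = struc2vec_embed(c6, d=8, K=2, walks_per_node=10, walk_length=20,
                                window=4, epochs=3, seed=seed).Z
            dists = [np.linalg.norm(z[i] - z[j]) for i in range(6) for j in range(i + 1, 6)]
            ratios.append(max(dists) / np.median(dists))
        assert np.mean(ratios) < 2.0

    def test_barbell_hubs_share_structural_role(self, barbell):
        # clique nodes of the two K4s are each other's structural twins;
        # they should sit closer to each other than to path midpoints
        hub_hub, hub_path = [], []
        for seed in range(5):
            z = struc2vec_embed(barbell, d=8, K=2, walks_per_node=10, walk_length=20,
                                window=4, epochs=3, seed=seed).Z
            hubs_a = [1, 2, 3]  # clique-internal nodes of block 1
            hubs_b = [5, 6, 7]  # clique-internal nodes of block 2
            mid = 9  # path midpoint
            hub_hub.append(np.mean([np.linalg.norm(z[i] - z[j]) for i in hubs_a for j in hubs_b]))
            hub_path.append(np.mean([np.linalg.norm(z[i] - z[mid]) for i in hubs_a + hubs_b]))
        assert np.mean(hub_hub) < np.mean(hub_path)
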