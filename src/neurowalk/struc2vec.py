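"""Structural-role embeddings (struc2vec).

Nodes are compared by their k-hop degree sequences R_k(v): the sorted
degrees of all nodes at exactly hop distance k.  A structural distance
accumulates over layers,

    w_k(v_i, v_j) = w_{k-1}(v_i, v_j) + d(R_k(v_i), R_k(v_j)),

with d(.,.) a dynamic-time-warping alignment whose per-pair cost is
max(a, b)/min(a, b) - 1.  Each layer k then defines a complete similarity
graph with transition weights exp(-w_k) — structurally similar pairs get
high transition probability — on which first-order walks are run; the
per-layer corpora are concatenated and fed to the skip-gram trainer.
Nodes with similar structural roles embed nearby regardless of their
graph distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path
from sklearn.base import BaseEstimator, TransformerMixin

from .types import BrainGraph
from .skipgram import EmbeddingMatrix, SkipGramParams, train_skipgram
from .walks import WalkCorpus, WalkParams, generate_walks


@dataclass
class DegreeSequence:
    node: int
    k: int
    R_k: list  # ascending degrees of nodes at exactly distance k (may be empty)


@dataclass
class LayerGraphs:
    K: int
    W: list  # [w_0 .. w_K], each N x N symmetric nonnegative, zero diagonal


def hop_distances(graph: BrainGraph) -> np.ndarray:
    """All-pairs hop distances on the unweighted nonzero-edge skeleton."""
    skel = (graph.adjacency > 0).astype(float)
    return shortest_path(skel, method="D", unweighted=True)


def degree_sequence(graph: BrainGraph, node: int, k: int, dist: np.ndarray | None = None
                    ) -> DegreeSequence:
    """Sorted degrees of the nodes at exactly k hops from ``node``."""
    if k < 0:
        raise ValueError("k must be >= 0")
    deg = graph.degrees()
    if k == 0:
        return DegreeSequence(node=node, k=0, R_k=[int(deg[node])])
    if dist is None:
        dist = hop_distances(graph)
    ring = np.nonzero(dist[node] == k)[0]
    return DegreeSequence(node=node, k=k, R_k=sorted(int(deg[v]) for v in ring))


def _pair_cost(a: float, b: float) -> float:
    return max(a, b) / min(a, b) - 1.0


def sequence_distance(r_a, r_b) -> float:
    """DTW alignment cost between two degree sequences.

    One empty sequence costs the nonempty one aligned against degree 1;
    two empty sequences cost 0.
    """
    a = [int(x) for x in (r_a.R_k if isinstance(r_a, DegreeSequence) else r_a)]
    b = [int(x) for x in (r_b.R_k if isinstance(r_b, DegreeSequence) else r_b)]
    if any(x < 0 for x in a + b):
        raise ValueError("degrees must be nonnegative")
    if not a and not b:
        return 0.0
    if not a or not b:
        seq = a or b
        return float(sum(_pair_cost(max(x, 1), 1) for x in seq))
    na, nb = len(a), len(b)
    d = np.full((na + 1, nb + 1), np.inf)
    d[0, 0] = 0.0
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            c = _pair_cost(max(a[i - 1], 1), max(b[j - 1], 1))
            d[i, j] = c + min(d[i - 1, j], d[i, j - 1], d[i - 1, j - 1])
    return float(d[na, nb])


def build_layer_graphs(graph: BrainGraph, K: int) -> LayerGraphs:
    """Accumulated structural distances w_0..w_K over all node pairs.

    K is capped at the (finite) graph diameter; beyond it every ring is
    empty and layers would only add the empty-sequence penalty
    symmetrically.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    n = graph.n_nodes
    dist = hop_distances(graph)
    finite = dist[np.isfinite(dist)]
    diameter = int(finite.max()) if finite.size else 0
    K = min(K, max(1, diameter))
    seqs = {
        (v, k): degree_sequence(graph, v, k, dist).R_k
        for v in range(n)
        for k in range(1, K + 1)
    }
    w = [np.zeros((n, n))]
    for k in range(1, K + 1):
        wk = w[-1].copy()
        for i in range(n):
            for j in range(i + 1, n):
                c = sequence_distance(seqs[(i, k)], seqs[(j, k)])
                wk[i, j] += c
                wk[j, i] += c
        w.append(wk)
    return LayerGraphs(K=K, W=w)


def _layer_similarity_graph(wk: np.ndarray) -> BrainGraph:
    s = np.exp(-wk)
    np.fill_diagonal(s, 0.0)
    return BrainGraph(nodes=list(range(wk.shape[0])), adjacency=s)


def struc2vec_embed(
    graph: BrainGraph,
    d: int = 64,
    K: int = 3,
    walks_per_node: int = 10,
    walk_length: int = 80,
    window: int = 10,
    negatives: int = 5,
    epochs: int = 5,
    seed: int = 0,
) -> EmbeddingMatrix:
    """Walks on the similarity graphs of layers 0..K, concatenated, + SGNS."""
    layers = build_layer_graphs(graph, K)
    walks = []
    for k, wk in enumerate(layers.W):
        sim = _layer_similarity_graph(wk)
        wp = WalkParams(
            walks_per_node=walks_per_node,
            walk_length=walk_length,
            p=1.0,
            q=1.0,
            seed=seed + 1000 * k,
        )
        walks.extend(generate_walks(sim, wp).walks)
    corpus = WalkCorpus(walks=walks, source_graph=graph)
    sg = SkipGramParams(window=window, negatives=negatives, epochs=epochs, seed=seed)
    emb = train_skipgram(corpus, d, sg)
    emb.method = "struc2vec"
    return emb


class Struc2VecEmbedding(BaseEstimator, TransformerMixin):
    """Per-graph struc2vec transformer: list of BrainGraph -> (n, N, d)."""

    def __init__(
        self,
        d: int = 64,
        K: int = 3,
        walks_per_node: int = 10,
        walk_length: int = 80,
        window: int = 10,
        negatives: int = 5,
        epochs: int = 5,
        seed: int = 0,
    ):
        self.d = d
        self.K = K
        self.walks_per_node = walks_per_node
        self.walk_length = walk_length
        self.window = window
        self.negatives = negatives
        self.epochs = epochs
        self.seed = seed

    def fit(self, X=None, y=None):
        return self

    def embed_one(self, graph: BrainGraph) -> EmbeddingMatrix:
        return struc2vec_embed(
            graph,
            d=self.d,
            K=self.K,
            walks_per_node=self.walks_per_node,
            walk_length=self.walk_length,
            window=self.window,
            negatives=self.negatives,
            epochs=self.epochs,
            seed=self.seed,
        )

    def transform(self, graphs) -> np.ndarray:
        return np.stack([self.embed_one(g).Z for g in graphs])
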