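"""DeepWalk / node2vec embedding estimators over BrainGraphs.

DeepWalk is node2vec with p = q = 1 at the walk level (uniform-by-weight
first-order walks); both feed the same skip-gram trainer.  The
transformers are stateless across subjects — each subject's embedding is
computed from that subject's graph alone, so they can be precomputed and
cached without leaking information between cross-validation folds.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .types import BrainGraph
from .skipgram import EmbeddingMatrix, SkipGramParams, train_skipgram
from .walks import WalkParams, generate_walks


def node2vec_embed(
    graph: BrainGraph,
    d: int = 25,
    p: float = 1.0,
    q: float = 1.0,
    walks_per_node: int = 10,
    walk_length: int = 80,
    window: int = 10,
    negatives: int = 5,
    epochs: int = 5,
    seed: int = 0,
) -> EmbeddingMatrix:
    """Second-order biased walks + SGNS; returns an N x d EmbeddingMatrix."""
    wp = WalkParams(
        walks_per_node=walks_per_node, walk_length=walk_length, p=p, q=q, seed=seed
    )
    corpus = generate_walks(graph, wp)
    sg = SkipGramParams(window=window, negatives=negatives, epochs=epochs, seed=seed)
    emb = train_skipgram(corpus, d, sg)
    emb.method = "node2vec" if (p, q) != (1.0, 1.0) else "deepwalk"
    return emb


def deepwalk_embed(graph: BrainGraph, d: int = 25, **kwargs) -> EmbeddingMatrix:
    """First-order weighted walks + SGNS (node2vec with p = q = 1)."""
    kwargs.pop("p", None)
    kwargs.pop("q", None)
    return node2vec_embed(graph, d=d, p=1.0, q=1.0, **kwargs)


class Node2VecEmbedding(BaseEstimator, TransformerMixin):
    """Per-graph node2vec transformer: list of BrainGraph -> (n, N, d)."""

    def __init__(
        self,
        d: int = 25,
        p: float = 1.0,
        q: float = 1.0,
        walks_per_node: int = 10,
        walk_length: int = 80,
        window: int = 10,
        negatives: int = 5,
        epochs: int = 5,
        seed: int = 0,
    ):
        self.d = d
        self.p = p
        self.q = q
        self.walks_per_node = walks_per_node
        self.walk_length = walk_length
        self.window = window
        self.negatives = negatives
        self.epochs = epochs
        self.seed = seed

    def fit(self, X=None, y=None):
        return self  # stateless across subjects

    def embed_one(self, graph: BrainGraph) -> EmbeddingMatrix:
        return node2vec_embed(
            graph,
            d=self.d,
            p=self.p,
            q=self.q,
            walks_per_node=self.walks_per_node,
            walk_length=self.walk_length,
            window=self.window,
            negatives=self.negatives,
            epochs=self.epochs,
            seed=self.seed,
        )

    def transform(self, graphs) -> np.ndarray:
        return np.stack([self.embed_one(g).Z for g in graphs])


class DeepWalkEmbedding(Node2VecEmbedding):
    """Node2VecEmbedding fixed at p = q = 1."""

    def __init__(
        self,
        d: int = 25,
        walks_per_node: int = 10,
        walk_length: int = 80,
        window: int = 10,
        negatives: int = 5,
        epochs: int = 5,
        seed: int = 0,
    ):
        super().__init__(
            d=d,
            p=1.0,
            q=1.0,
            walks_per_node=walks_per_node,
            walk_length=walk_length,
            window=window,
            negatives=negatives,
            epochs=epochs,
            seed=seed,
        )
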