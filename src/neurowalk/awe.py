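"""Anonymous Walk Embeddings (AWE), feature-based, per node.

A walk (v_1, ..., v_k) is anonymized by replacing each node with the
1-based index of its first occurrence — (v7, v3, v7, v5) becomes
(1, 2, 1, 3) — so the pattern captures the walk's structure while
discarding node identities.  For a node u, the AWE feature vector is the
empirical distribution of anonymized patterns over eta weighted random
walks of edge-length l started at u, indexed against the canonical
(lexicographic) enumeration of all valid patterns of that length.

The number of patterns grows like the Bell numbers (1, 2, 5, 15, 52,
203 for l = 1..6), so a 128-dimensional per-node vector is formed by
concatenating the complete distributions for l = 4 (15 types) and l = 5
(52 types) with the 61 lexicographically-first types of l = 6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .types import BrainGraph
from .skipgram import EmbeddingMatrix

logger = logging.getLogger(__name__)

_ENUM_CAP = 10
AWE_LENGTH_COMPOSITION = ((4, 15), (5, 52), (6, 61))  # (l, n_types kept) -> 128 dims


@dataclass
class AnonymousWalk:
    pattern: tuple  # (f(v_1), ..., f(v_k)), first element 1

    @property
    def length(self) -> int:
        """Edge count."""
        return len(self.pattern) - 1


@dataclass
class AWEVector:
    node: int
    l: int
    eta: int
    probs: np.ndarray  # over the canonical type ordering (possibly truncated/padded)


def anonymize(walk) -> AnonymousWalk:
    """Replace each node by the 1-based index of its first occurrence."""
    walk = list(walk)
    if not walk:
        raise ValueError("empty walk")
    first_seen = {}
    pattern = []
    for i, v in enumerate(walk):
        if i > 0 and v == walk[i - 1]:
            raise ValueError(f"consecutive repeat at position {i}: not a valid walk")
        if v not in first_seen:
            first_seen[v] = len(first_seen) + 1
        pattern.append(first_seen[v])
    return AnonymousWalk(pattern=tuple(pattern))


@lru_cache(maxsize=None)
def _enumerate(l: int) -> tuple:
    if l == 0:
        return ((1,),)
    out = []
    for prefix in _enumerate(l - 1):
        hi = max(prefix)
        for nxt in range(1, hi + 2):
            if nxt != prefix[-1]:
                out.append(prefix + (nxt,))
    return tuple(sorted(out))


def enumerate_walk_types(l: int):
    """All valid anonymous-walk patterns of edge-length l, lexicographic."""
    if l < 1:
        raise ValueError("l must be >= 1")
    if l > _ENUM_CAP:
        raise ValueError(f"l={l} exceeds the enumeration cap {_ENUM_CAP}")
    return [AnonymousWalk(pattern=p) for p in _enumerate(l)]


def _sample_patterns(
    graph: BrainGraph, node: int, l: int, eta: int, rng: np.random.Generator
) -> np.ndarray:
    """eta weighted walks of edge-length l from ``node``; returns an
    (eta, l+1) array of anonymized patterns, vectorized over walks."""
    a = graph.adjacency
    n = graph.n_nodes
    cum = []
    ok = np.zeros(n, dtype=bool)
    for v in range(n):
        w = a[v]
        s = w.sum()
        cum.append(np.cumsum(w) / s if s > 0 else None)
        ok[v] = s > 0
    cur = np.full(eta, node, dtype=np.int64)
    pat = np.ones((eta, l + 1), dtype=np.int64)
    seen_count = np.ones(eta, dtype=np.int64)
    # first-occurrence index bookkeeping per walk
    first = -np.ones((eta, n), dtype=np.int64)
    first[:, node] = 1
    for step in range(1, l + 1):
        u = rng.random(eta)
        nxt = np.empty(eta, dtype=np.int64)
        for v in np.unique(cur):
            mask = cur == v
            nxt[mask] = np.searchsorted(cum[v], u[mask])
        new = first[np.arange(eta), nxt] < 0
        seen_count[new] += 1
        first[np.arange(eta)[new], nxt[new]] = seen_count[new]
        pat[:, step] = first[np.arange(eta), nxt]
        cur = nxt
    return pat


def awe_node_features(
    graph: BrainGraph,
    node: int,
    l: int,
    eta: int = 10_000,
    seed: int = 0,
    d: int | None = None,
) -> AWEVector:
    """Empirical anonymous-walk-type distribution for one node.

    Isolated nodes get a zero vector (with a warning); otherwise the
    untruncated probabilities sum to one.  ``d`` truncates or zero-pads
    the vector to a fixed dimension.
    """
    if eta < 1:
        raise ValueError("eta must be >= 1")
    types = enumerate_walk_types(l)
    index = {t.pattern: i for i, t in enumerate(types)}
    if graph.adjacency[node].sum() <= 0:
        logger.warning("node %s is isolated; AWE vector is zero", node)
        probs = np.zeros(len(types))
    else:
        rng = np.random.default_rng(seed)
        pat = _sample_patterns(graph, node, l, eta, rng)
        probs = np.zeros(len(types))
        keys, counts = np.unique(pat, axis=0, return_counts=True)
        for key, cnt in zip(keys, counts):
            probs[index[tuple(key)]] += cnt
        probs /= eta
    if d is not None:
        if d <= len(probs):
            probs = probs[:d]
        else:
            probs = np.pad(probs, (0, d - len(probs)))
    return AWEVector(node=node, l=l, eta=eta, probs=probs)


def awe_embed(
    graph: BrainGraph,
    eta: int = 10_000,
    seed: int = 0,
    d: int = 128,
    composition=AWE_LENGTH_COMPOSITION,
) -> EmbeddingMatrix:
    """Stacked per-node AWE features (default 39 x 128).

    The default composition concatenates the full distributions for
    l = 4 and l = 5 and the first 61 types of l = 6; other target
    dimensions reuse the same lengths with the final block truncated or
    padded to fit.
    """
    total = sum(k for _, k in composition)
    if total != d:
        # refit the composition to the requested dimension: take the same
        # walk lengths in order, truncating the block that overflows
        remaining = d
        refit = []
        for l, k in composition:
            take = min(k, remaining)
            if take > 0:
                refit.append((l, take))
            remaining -= take
        if remaining > 0:  # d larger than the full composition: pad last block
            l, k = refit[-1]
            refit[-1] = (l, k + remaining)
        composition = tuple(refit)
    rows = []
    for v in range(graph.n_nodes):
        parts = []
        for i, (l, k) in enumerate(composition):
            vec = awe_node_features(graph, v, l, eta=eta, seed=seed + 7919 * i, d=k)
            parts.append(vec.probs)
        rows.append(np.concatenate(parts))
    z = np.stack(rows)
    return EmbeddingMatrix(method="awe", Z=z, d=z.shape[1])


def exact_awe_distribution(graph: BrainGraph, node: int, l: int) -> np.ndarray:
    """Exact anonymous-walk-type distribution by full walk enumeration.

    Exponential in l; intended for small graphs (oracle/validation use).
    """
    a = graph.adjacency
    types = enumerate_walk_types(l)
    index = {t.pattern: i for i, t in enumerate(types)}
    probs = np.zeros(len(types))

    def recurse(path, prob):
        if len(path) == l + 1:
            probs[index[anonymize(path).pattern]] += prob
            return
        v = path[-1]
        w = a[v]
        s = w.sum()
        if s <= 0:
            return
        for u in np.nonzero(w > 0)[0]:
            recurse(path + [int(u)], prob * w[u] / s)

    recurse([node], 1.0)
    return probs


class AWEmbedding(BaseEstimator, TransformerMixin):
    """Per-graph AWE transformer: list of BrainGraph -> (n, N, d)."""

    def __init__(self, d: int = 128, eta: int = 10_000, seed: int = 0):
        self.d = d
        self.eta = eta
        self.seed = seed

    def fit(self, X=None, y=None):
        return self

    def embed_one(self, graph: BrainGraph) -> EmbeddingMatrix:
        return awe_embed(graph, eta=self.eta, seed=self.seed, d=self.d)

    def transform(self, graphs) -> np.ndarray:
        return np.stack([self.embed_one(g).Z for g in graphs])
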