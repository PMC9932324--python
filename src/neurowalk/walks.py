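"""Random-walk corpus generation: first-order weighted walks (DeepWalk)
and second-order biased walks (node2vec).

The node2vec bias multiplies the edge weight w(current, candidate) by

    1/p  if candidate == previous node (return step),
    1    if candidate is adjacent to the previous node,
    1/q  otherwise (outward step),

so p penalizes immediate backtracking and q trades off breadth- vs
depth-like exploration.  With p = q = 1 the walk reduces exactly to the
first-order weighted walk.  Walk length counts nodes, not edges.
Sampling uses alias tables built lazily per (previous, current) pair:
O(degree) setup, O(1) per step afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import BrainGraph


@dataclass
class WalkParams:
    walks_per_node: int = 10
    walk_length: int = 80  # nodes per walk
    p: float = 1.0
    q: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.walks_per_node < 1:
            raise ValueError("walks_per_node must be >= 1")
        if self.walk_length < 2:
            raise ValueError("walk_length must be >= 2")
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")


@dataclass
class WalkCorpus:
    walks: list  # of lists of node indices
    source_graph: BrainGraph = None


def node2vec_bias(prev_node, current_node, candidate, graph: BrainGraph, p: float, q: float):
    """Unnormalized second-order transition weight w(current, candidate) * alpha."""
    if p <= 0 or q <= 0:
        raise ValueError("p and q must be positive")
    w = graph.adjacency[current_node, candidate]
    if w <= 0:
        raise ValueError(f"({current_node}, {candidate}) is not an edge")
    if candidate == prev_node:
        alpha = 1.0 / p
    elif graph.adjacency[prev_node, candidate] > 0:
        alpha = 1.0
    else:
        alpha = 1.0 / q
    return w * alpha


class AliasSampler:
    """Walker's alias method: O(1) categorical sampling after O(k) setup."""

    def __init__(self, probs: np.ndarray):
        probs = np.asarray(probs, dtype=float)
        k = probs.size
        self.k = k
        scaled = probs * k / probs.sum()
        self.prob = np.zeros(k)
        self.alias = np.zeros(k, dtype=np.int64)
        small = [i for i in range(k) if scaled[i] < 1.0]
        large = [i for i in range(k) if scaled[i] >= 1.0]
        while small and large:
            s, l = small.pop(), large.pop()
            self.prob[s] = scaled[s]
            self.alias[s] = l
            scaled[l] = scaled[l] - (1.0 - scaled[s])
            (small if scaled[l] < 1.0 else large).append(l)
        for rest in (large, small):
            while rest:
                self.prob[rest.pop()] = 1.0

    def sample(self, rng: np.random.Generator) -> int:
        i = int(rng.integers(self.k))
        return i if rng.random() < self.prob[i] else int(self.alias[i])


class _WalkEngine:
    """Caches neighbor lists and alias tables for one graph."""

    def __init__(self, graph: BrainGraph, p: float, q: float):
        self.graph = graph
        self.p = p
        self.q = q
        a = graph.adjacency
        self.neighbors = [np.nonzero(a[v] > 0)[0] for v in range(graph.n_nodes)]
        self.first_order = {}
        self.second_order = {}

    def _first(self, v: int) -> AliasSampler:
        if v not in self.first_order:
            nb = self.neighbors[v]
            self.first_order[v] = AliasSampler(self.graph.adjacency[v, nb])
        return self.first_order[v]

    def _second(self, prev: int, cur: int) -> AliasSampler:
        key = (prev, cur)
        if key not in self.second_order:
            nb = self.neighbors[cur]
            a = self.graph.adjacency
            w = a[cur, nb].copy()
            alpha = np.where(
                nb == prev, 1.0 / self.p, np.where(a[prev, nb] > 0, 1.0, 1.0 / self.q)
            )
            self.second_order[key] = AliasSampler(w * alpha)
        return self.second_order[key]

    def walk(self, start: int, length: int, rng: np.random.Generator) -> list:
        if self.neighbors[start].size == 0:
            return [start]  # isolated node -> singleton walk
        path = [start]
        cur = start
        nxt = self.neighbors[cur][self._first(cur).sample(rng)]
        path.append(int(nxt))
        while len(path) < length:
            prev, cur = path[-2], path[-1]
            if self.neighbors[cur].size == 0:
                break
            if self.p == 1.0 and self.q == 1.0:
                step = self.neighbors[cur][self._first(cur).sample(rng)]
            else:
                step = self.neighbors[cur][self._second(prev, cur).sample(rng)]
            path.append(int(step))
        return path


def generate_walks(graph: BrainGraph, params: WalkParams) -> WalkCorpus:
    """walks_per_node walks from every node; first step by edge weight,
    later steps by the node2vec bias."""
    if graph.n_nodes == 0:
        raise ValueError("graph is empty")
    engine = _WalkEngine(graph, params.p, params.q)
    rng = np.random.default_rng(params.seed)
    walks = []
    for _ in range(params.walks_per_node):
        for v in range(graph.n_nodes):
            walks.append(engine.walk(v, params.walk_length, rng))
    return WalkCorpus(walks=walks, source_graph=graph)


def transition_matrix(graph: BrainGraph) -> np.ndarray:
    """Weight-normalized first-order transition law (rows sum to 1)."""
    a = graph.adjacency
    row = a.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(row > 0, a / row, 0.0)
    return t
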