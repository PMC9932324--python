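"""Connectivity matrices -> weighted undirected graphs for random walks.

Random-walk transition probabilities need nonnegative weights, so
negative correlations must be transformed; the default takes absolute
values (treating under- and over-connectivity as equally informative
edge strength).  Optional sparsification keeps the top fraction of edges
by weight with deterministic lexicographic tie-breaking.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import networkx as nx

from .types import BrainGraph, ConnectivityMatrix

logger = logging.getLogger(__name__)

_TRANSFORMS = ("abs", "positive_only", "shift_min")


def connectivity_to_graph(
    cm: ConnectivityMatrix,
    weight_transform: str = "abs",
    density: float | None = None,
) -> BrainGraph:
    """Build a BrainGraph from one connectivity matrix.

    weight_transform:
      * ``abs`` — |w| (default),
      * ``positive_only`` — negative entries dropped to 0,
      * ``shift_min`` — w - min(w) over off-diagonals (min maps to 0).

    density, if given, keeps the top ceil(density * N(N-1)/2) edges.
    """
    if weight_transform not in _TRANSFORMS:
        raise ValueError(f"weight_transform must be one of {_TRANSFORMS}")
    a = np.array(cm.values, dtype=float)
    np.fill_diagonal(a, 0.0)
    if weight_transform == "abs":
        a = np.abs(a)
    elif weight_transform == "positive_only":
        a = np.maximum(a, 0.0)
    else:  # shift_min
        off = a[~np.eye(a.shape[0], dtype=bool)]
        a = a - off.min()
        np.fill_diagonal(a, 0.0)
        a = np.maximum(a, 0.0)

    n = a.shape[0]
    if density is not None:
        if not (0 < density <= 1):
            raise ValueError(f"density must be in (0, 1], got {density}")
        m = n * (n - 1) // 2
        keep = math.ceil(density * m)
        iu, ju = np.triu_indices(n, k=1)
        w = a[iu, ju]
        # sort by weight desc, then (i, j) lexicographic for determinism
        order = sorted(range(m), key=lambda k: (-w[k], iu[k], ju[k]))
        mask = np.zeros((n, n), dtype=bool)
        for k in order[:keep]:
            mask[iu[k], ju[k]] = mask[ju[k], iu[k]] = True
        a = np.where(mask, a, 0.0)

    graph = BrainGraph(nodes=list(range(n)), adjacency=a)
    isolated = np.nonzero(graph.degrees() == 0)[0]
    if isolated.size:
        logger.warning(
            "subject %s: isolated node(s) %s after transform", cm.subject_id, isolated.tolist()
        )
    return graph


def to_networkx(graph: BrainGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    for i, j in graph.edges():
        g.add_edge(graph.nodes[i], graph.nodes[j], weight=float(graph.adjacency[i, j]))
    return g


def write_edge_list(graph: BrainGraph, path) -> None:
    """Weighted edge list TSV: i, j, w."""
    with open(path, "w") as fh:
        fh.write("i\tj\tweight\n")
        for i, j in graph.edges():
            fh.write(f"{graph.nodes[i]}\t{graph.nodes[j]}\t{graph.adjacency[i, j]:.10g}\n")


def write_graphml(graph: BrainGraph, path) -> None:
    nx.write_graphml(to_networkx(graph), path)
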