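import numpy as np
import pytest

from neurowalk.types import BrainGraph, ROITimeSeries
from neurowalk.synthetic import CohortConfig, simulate_cohort


def graph_from_edges(n, edges, weights=None):
    a = np.zeros((n, n))
    for k, (i, j) in enumerate(edges):
        w = 1.0 if weights is None else weights[k]
        a[i, j] = a[j, i] = w
    return BrainGraph(nodes=list(range(n)), adjacency=a)


@pytest.fixture
def triangle():
    return graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def c6():
    """6-cycle: vertex-transitive, all nodes structurally identical."""
    return graph_from_edges(6, [(i, (i + 1) % 6) for i in range(6)])


@pytest.fixture
def star4():
    """Star with 4 leaves; node 0 is the center."""
    return graph_from_edges(5, [(0, i) for i in range(1, 5)])


@pytest.fixture
def barbell():
    """Two K4 cliques joined by a 3-node path (nodes 8, 9, 10)."""
    edges = []
    for block in (range(0, 4), range(4, 8)):
        block = list(block)
        edges += [(i, j) for i in block for j in block if i < j]
    edges += [(0, 8), (8, 9), (9, 10), (10, 4)]
    return graph_from_edges(11, edges)


@pytest.fixture(scope="session")
def small_cohort():
    """Two-site, 10-ROI toy cohort with a clear class effect."""
    cfg = CohortConfig(
        n_sites=2,
        subjects_per_site_per_class=4,
        n_rois=10,
        n_timepoints=80,
        n_modules=2,
        n_effect_edges=6,
        class_effect=0.4,
        site_effect=0.05,
        seed=3,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def random_ts():
    rng = np.random.default_rng(42)
    return ROITimeSeries(
        subject_id="sub_rand",
        site_id="site_x",
        label="control",
        data=rng.standard_normal((50, 3)),
    )
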