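"""Shared in-memory containers for the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LABELS = ("control", "ASD")  # index 0 = control (negative), 1 = ASD (positive)


@dataclass
class ROITimeSeries:
    """One subject's ROI time series: ``data`` is timepoints x ROIs."""

    subject_id: str
    site_id: str
    label: str  # "ASD", "control" or "unknown"
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError(
                f"subject {self.subject_id}: time series must be T x N with T >= 2, "
                f"got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"subject {self.subject_id}: non-finite values in time series")
        if self.label not in ("ASD", "control", "unknown"):
            raise ValueError(f"subject {self.subject_id}: unknown label {self.label!r}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N connectivity values for one subject.

    Pearson/partial entries live in [-1, 1] with unit diagonal; tangent
    matrices are symmetric but unbounded.
    """

    subject_id: str
    kind: str  # "pearson" | "partial" | "tangent"
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"connectivity must be square, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError(f"subject {self.subject_id}: connectivity not symmetric")
        if self.kind in ("pearson", "partial"):
            if not np.allclose(np.diag(v), 1.0, atol=1e-10):
                raise ValueError(f"subject {self.subject_id}: {self.kind} diagonal must be 1")
            if np.any(np.abs(v) > 1.0 + 1e-12):
                raise ValueError(f"subject {self.subject_id}: {self.kind} entries exceed [-1, 1]")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class BrainGraph:
    """Weighted undirected graph over the ROI nodes.

    ``adjacency`` is symmetric, nonnegative, zero-diagonal; node order is
    fixed cohort-wide so embedding rows line up across subjects.
    """

    nodes: list = field(default_factory=list)
    adjacency: np.ndarray = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        a = self.adjacency
        n = len(self.nodes)
        if a.shape != (n, n):
            raise ValueError(f"adjacency shape {a.shape} does not match {n} nodes")
        if not np.allclose(a, a.T, atol=1e-10):
            raise ValueError("adjacency not symmetric")
        if np.any(a < 0):
            raise ValueError("negative edge weights")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def edges(self) -> list:
        """Edge list {(i, j): A_ij > 0, i < j} as index pairs."""
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(i.tolist(), j.tolist()))

    def degrees(self) -> np.ndarray:
        """Unweighted degrees on the nonzero-edge skeleton."""
        return (self.adjacency > 0).sum(axis=1)
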