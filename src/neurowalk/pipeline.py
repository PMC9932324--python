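"""End-to-end scenario pipelines: time series in, diagnosis out.

Three input scenarios feed the LeNet-variant classifier:

* ``s1`` — one channel, the N x d node-embedding matrix of a single
  method (node2vec / deepwalk / struc2vec / AWE); shape (1, 39, d).
* ``s2`` — three channels, node2vec embeddings at (p, q) = (1, 1),
  (1, 4) and (4, 1); shape (3, 39, 25).
* ``s3`` — two channels, the Graph2Img rasterization (M12, M34) of a
  PCA-reduced node2vec embedding; shape (2, 10, 10).

Every statistic fitted on data — the tangent reference, Graph2Img
bounds, per-channel normalization — is fitted on the training subjects
only and records which subjects it touched, so the cross-validation
harness can assert the absence of leakage.  Per-subject embeddings
depend only on that subject's own graph and a fixed seed, so they are
memoized in a cache shared across folds.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .types import ROITimeSeries
from .connectivity import ConnectivityExtractor
from .graph import connectivity_to_graph
from .embeddings import node2vec_embed
from .struc2vec import struc2vec_embed
from .awe import awe_embed
from .graph2img import Graph2Img
from .nn import LeNetClassifier

SCENARIOS = ("s1", "s2", "s3")
S2_PQ = ((1.0, 1.0), (1.0, 4.0), (4.0, 1.0))


class ChannelScaler(BaseEstimator):
    """Per-channel z-score using training-split statistics."""

    def fit(self, X, y=None, subject_ids=None):
        x = np.asarray(X, dtype=float)
        self.mean_ = x.mean(axis=(0, 2, 3), keepdims=True)
        self.std_ = x.std(axis=(0, 2, 3), keepdims=True)
        self.std_[self.std_ == 0] = 1.0
        self.fit_subjects_ = list(subject_ids) if subject_ids is not None else list(
            range(x.shape[0])
        )
        return self

    def transform(self, X):
        return (np.asarray(X, dtype=float) - self.mean_) / self.std_


def build_scenario_tensor(embeddings: dict, scenario: str) -> np.ndarray:
    """Stack one subject's embedding artifacts into the scenario tensor.

    ``embeddings`` maps channel names to arrays: scenario s1 expects
    {"embedding": N x d}; s2 expects {"pq_1_1", "pq_1_4", "pq_4_1"} each
    N x d; s3 expects {"M12", "M34"} each r x r.
    """
    if scenario == "s1":
        if "embedding" not in embeddings:
            raise KeyError("scenario s1 needs channel 'embedding'")
        return np.asarray(embeddings["embedding"], dtype=float)[None]
    if scenario == "s2":
        chans = []
        for p, q in S2_PQ:
            key = f"pq_{p:g}_{q:g}"
            if key not in embeddings:
                raise KeyError(f"scenario s2 missing channel {key!r}")
            chans.append(np.asarray(embeddings[key], dtype=float))
        return np.stack(chans)
    if scenario == "s3":
        for key in ("M12", "M34"):
            if key not in embeddings:
                raise KeyError(f"scenario s3 missing channel {key!r}")
        return np.stack(
            [np.asarray(embeddings["M12"], float), np.asarray(embeddings["M34"], float)]
        )
    raise ValueError(f"scenario must be one of {SCENARIOS}, got {scenario!r}")


class GraphEmbeddingPipeline(BaseEstimator, ClassifierMixin):
    """Full classifier: ROI time series -> connectivity -> graph ->
    embedding -> scenario tensor -> LeNet variant.

    Parameters
    ----------
    scenario : {"s1", "s2", "s3"}
    embedding_method : {"node2vec", "deepwalk", "struc2vec", "awe"}
        Used by scenario s1 (s2 and s3 always use node2vec).
    connectivity_kind : {"pearson", "partial", "tangent"}
    d : embedding dimension for s1/s2 channels (the standard scenarios
        use 25 for node2vec, 64 for struc2vec, 128 for AWE).
    walks_per_node, walk_length, window, epochs_sg : walk/SGNS budget.
    eta : AWE walks per node (method "awe" only).
    cnn_epochs, cnn_patience, batch_size, learning_rate : CNN training.
    embedding_cache : optional dict shared across folds; keys include
        the subject id and all embedding hyperparameters.
    """

    def __init__(
        self,
        scenario: str = "s3",
        embedding_method: str = "node2vec",
        connectivity_kind: str = "pearson",
        weight_transform: str = "abs",
        density: float | None = None,
        d: int = 25,
        p: float = 1.0,
        q: float = 1.0,
        K: int = 3,
        eta: int = 1000,
        walks_per_node: int = 10,
        walk_length: int = 80,
        window: int = 10,
        epochs_sg: int = 5,
        r: int = 10,
        d_pca: int = 4,
        cell_value: str = "strength",
        cnn_epochs: int = 100,
        cnn_patience: int | None = 15,
        validation_fraction: float = 0.2,
        batch_size: int = 16,
        learning_rate: float = 1e-3,
        seed: int = 0,
        embedding_cache: dict | None = None,
    ):
        self.scenario = scenario
        self.embedding_method = embedding_method
        self.connectivity_kind = connectivity_kind
        self.weight_transform = weight_transform
        self.density = density
        self.d = d
        self.p = p
        self.q = q
        self.K = K
        self.eta = eta
        self.walks_per_node = walks_per_node
        self.walk_length = walk_length
        self.window = window
        self.epochs_sg = epochs_sg
        self.r = r
        self.d_pca = d_pca
        self.cell_value = cell_value
        self.cnn_epochs = cnn_epochs
        self.cnn_patience = cnn_patience
        self.validation_fraction = validation_fraction
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed
        self.embedding_cache = embedding_cache

    # -- embedding plumbing -------------------------------------------------

    def _walk_kwargs(self):
        return dict(
            walks_per_node=self.walks_per_node,
            walk_length=self.walk_length,
            window=self.window,
            epochs=self.epochs_sg,
            seed=self.seed,
        )

    def _embed_subject(self, subject_id: str, graph) -> dict:
        """All embedding channels for one subject (memoized)."""
        key = (
            subject_id,
            self.scenario,
            self.embedding_method,
            self.connectivity_kind,
            self.weight_transform,
            self.density,
            self.d,
            self.p,
            self.q,
            self.K,
            self.eta,
            self.walks_per_node,
            self.walk_length,
            self.window,
            self.epochs_sg,
            self.seed,
        )
        cache = self.embedding_cache
        if cache is not None and key in cache:
            return cache[key]
        out = {}
        if self.scenario == "s2":
            for p, q in S2_PQ:
                emb = node2vec_embed(graph, d=self.d, p=p, q=q, **self._walk_kwargs())
                out[f"pq_{p:g}_{q:g}"] = emb.Z
        elif self.scenario == "s3" or (
            self.scenario == "s1" and self.embedding_method == "node2vec"
        ):
            emb = node2vec_embed(graph, d=self.d, p=self.p, q=self.q, **self._walk_kwargs())
            out["embedding"] = emb.Z
        elif self.embedding_method == "deepwalk":
            out["embedding"] = node2vec_embed(
                graph, d=self.d, p=1.0, q=1.0, **self._walk_kwargs()
            ).Z
        elif self.embedding_method == "struc2vec":
            out["embedding"] = struc2vec_embed(
                graph, d=self.d, K=self.K, **self._walk_kwargs()
            ).Z
        elif self.embedding_method == "awe":
            out["embedding"] = awe_embed(graph, eta=self.eta, seed=self.seed, d=self.d).Z
        else:
            raise ValueError(f"unknown embedding_method {self.embedding_method!r}")
        if cache is not None:
            cache[key] = out
        return out

    def _graphs(self, subjects, connectivity):
        cms = connectivity.transform(subjects)
        return [
            connectivity_to_graph(cm, self.weight_transform, self.density) for cm in cms
        ]

    def _tensors(self, subjects, graphs, fit: bool):
        ids = [s.subject_id for s in subjects]
        channels = [self._embed_subject(sid, g) for sid, g in zip(ids, graphs)]
        if self.scenario == "s3":
            embs = [c["embedding"] for c in channels]
            strengths = [g.adjacency.sum(axis=1) for g in graphs]
            if fit:
                self.graph2img_ = Graph2Img(
                    r=self.r, d_pca=self.d_pca, cell_value=self.cell_value
                )
                self.graph2img_.fit(embs, subject_ids=ids)
            imgs = self.graph2img_.transform(embs, node_strengths=strengths)
            tensors = [
                build_scenario_tensor({"M12": im[0], "M34": im[1]}, "s3") for im in imgs
            ]
        else:
            tensors = [build_scenario_tensor(c, self.scenario) for c in channels]
        return np.stack(tensors)

    # -- sklearn API --------------------------------------------------------

    def fit(self, subjects, y=None):
        if y is None:
            y = np.array([1 if s.label == "ASD" else 0 for s in subjects])
        y = np.asarray(y, dtype=int)
        self.connectivity_ = ConnectivityExtractor(kind=self.connectivity_kind)
        self.connectivity_.fit(subjects)
        graphs = self._graphs(subjects, self.connectivity_)
        x = self._tensors(subjects, graphs, fit=True)
        self.scaler_ = ChannelScaler().fit(x, subject_ids=[s.subject_id for s in subjects])
        x = self.scaler_.transform(x)
        self.classifier_ = LeNetClassifier(
            epochs=self.cnn_epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            early_stopping_patience=self.cnn_patience,
            validation_fraction=self.validation_fraction,
            seed=self.seed,
        )
        self.classifier_.fit(x, y)
        self.classes_ = self.classifier_.classes_
        return self

    def _transform(self, subjects):
        graphs = self._graphs(subjects, self.connectivity_)
        x = self._tensors(subjects, graphs, fit=False)
        return self.scaler_.transform(x)

    def predict(self, subjects):
        return self.classifier_.predict(self._transform(subjects))

    def predict_proba(self, subjects):
        return self.classifier_.predict_proba(self._transform(subjects))

    def fitted_subject_ids(self) -> dict:
        """Which subjects each fitted statistic touched (leakage audit)."""
        out = {}
        if hasattr(self, "connectivity_"):
            out["connectivity_reference"] = set(self.connectivity_.fit_subjects_)
        if hasattr(self, "graph2img_"):
            out["graph2img_bounds"] = set(self.graph2img_.fit_subjects_)
        if hasattr(self, "scaler_"):
            out["channel_scaler"] = set(self.scaler_.fit_subjects_)
        return out
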