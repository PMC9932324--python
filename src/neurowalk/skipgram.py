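"""Skip-gram with negative sampling (SGNS) over walk corpora.

A reference NumPy implementation: walks are the sentences, nodes the
vocabulary.  For every (center, context) pair within ``window`` the
model maximizes log sigma(z_c . z'_o) plus ``negatives`` negative terms
sampled from the unigram^{3/4} distribution; training is vectorized
minibatch SGD with a linearly decaying learning rate, single-threaded
and fully deterministic under a fixed seed.  Embeddings are the input
vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .walks import WalkCorpus


@dataclass
class SkipGramParams:
    window: int = 10
    negatives: int = 5
    epochs: int = 5
    learning_rate: float = 0.025
    batch_size: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 1 or self.negatives < 1 or self.epochs < 1:
            raise ValueError("window, negatives and epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class EmbeddingMatrix:
    """N x d node embedding; row order equals graph node order."""

    method: str
    Z: np.ndarray
    d: int
    loss_history: list = field(default_factory=list)


def _pairs_from_walks(walks, window: int):
    """All (center, context) index pairs within the window, both directions."""
    centers, contexts = [], []
    for walk in walks:
        w = np.asarray(walk, dtype=np.int64)
        n = w.size
        for off in range(1, min(window, n - 1) + 1):
            centers.append(w[:-off])
            contexts.append(w[off:])
            centers.append(w[off:])
            contexts.append(w[:-off])
    if not centers:
        raise ValueError("corpus contains no usable pairs (walks too short?)")
    return np.concatenate(centers), np.concatenate(contexts)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_skipgram(
    corpus: WalkCorpus, d: int, sg: SkipGramParams, n_nodes: int | None = None
) -> EmbeddingMatrix:
    """Train SGNS on a walk corpus and return the N x d embedding."""
    if n_nodes is None:
        n_nodes = corpus.source_graph.n_nodes if corpus.source_graph is not None else (
            max(max(w) for w in corpus.walks) + 1
        )
    centers, contexts = _pairs_from_walks(corpus.walks, sg.window)

    counts = np.bincount(np.concatenate([centers, contexts]), minlength=n_nodes).astype(float)
    missing = np.nonzero(counts == 0)[0]
    if missing.size:
        raise ValueError(f"node(s) {missing.tolist()} never appear in the corpus")
    noise = counts ** 0.75
    noise /= noise.sum()

    rng = np.random.default_rng(sg.seed)
    w_in = (rng.random((n_nodes, d)) - 0.5) / d
    w_out = np.zeros((n_nodes, d))
    noise_cdf = np.cumsum(noise)
    eye = np.eye(n_nodes)

    n_pairs = centers.size
    # cap the batch so each row's summed update stays bounded (~16 hits
    # per row per batch at most); small vocabularies diverge otherwise
    batch = min(sg.batch_size, 16 * n_nodes)
    total_steps = sg.epochs * n_pairs
    seen = 0
    loss_history = []
    for _ in range(sg.epochs):
        order = rng.permutation(n_pairs)
        epoch_loss = 0.0
        for lo in range(0, n_pairs, batch):
            idx = order[lo : lo + batch]
            c, o = centers[idx], contexts[idx]
            b = c.size
            neg = np.searchsorted(noise_cdf, rng.random((b, sg.negatives)))
            lr = sg.learning_rate * max(1e-4, 1.0 - seen / total_steps)
            seen += b

            h = w_in[c]  # (b, d)
            v_pos = w_out[o]  # (b, d)
            v_neg = w_out[neg]  # (b, k, d)

            s_pos = _sigmoid(np.einsum("bd,bd->b", h, v_pos))
            s_neg = _sigmoid(np.einsum("bd,bkd->bk", h, v_neg))
            epoch_loss += float(
                -(np.log(np.maximum(s_pos, 1e-12)).sum())
                - np.log(np.maximum(1.0 - s_neg, 1e-12)).sum()
            )

            g_pos = s_pos - 1.0  # (b,)
            g_neg = s_neg  # (b, k)

            grad_h = g_pos[:, None] * v_pos + np.einsum("bk,bkd->bd", g_neg, v_neg)
            # classic summed SGNS updates, accumulated densely via one-hot
            # matmuls (the vocabulary is tiny, so this beats scatter-adds)
            d_in = eye[c].T @ grad_h
            d_out = eye[o].T @ (g_pos[:, None] * h)
            flat = neg.reshape(-1)
            d_out += eye[flat].T @ (g_neg.reshape(-1, 1) * np.repeat(h, sg.negatives, axis=0))
            w_in -= lr * d_in
            w_out -= lr * d_out
        loss_history.append(epoch_loss / n_pairs)

    if not np.all(np.isfinite(w_in)):
        raise RuntimeError("skip-gram training diverged (non-finite embeddings)")
    return EmbeddingMatrix(method="skipgram", Z=w_in, d=d, loss_history=loss_history)
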