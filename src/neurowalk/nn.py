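"""LeNet-variant CNN in NumPy, shaped for the three scenario inputs.

Architecture: conv(64 filters) -> ReLU -> 2x2 max pool -> conv(96)
-> ReLU -> 2x2 max pool (skipped when a spatial dimension would vanish)
-> flatten -> dense 120 -> dropout -> ReLU -> dense 84 -> dropout ->
ReLU -> dense 2 -> softmax.  Kernels are 5x5 for inputs with height >=
20 (the 39 x d embedding scenarios) and 3x3 otherwise (the 10 x 10
Graph2Img scenario); convolutions use same-padding, stride 1.  Dropout
keeps 80% of units at the hidden dense layers (inverted dropout, so
inference is deterministic).  Training minimizes cross-entropy with
Adam; everything is single-threaded and deterministic under a fixed
seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Conv2D:
    """Same-padded stride-1 convolution via im2col + BLAS matmul."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_ch * k * k))
        self.W = rng.standard_normal((out_ch, in_ch, k, k)) * scale
        self.b = np.zeros(out_ch)
        self.k = k

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        k = self.k
        b, c, h, w = x.shape
        pl, pr = (k - 1) // 2, k // 2  # same padding
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr), (pl, pr)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B,C,H,W,k,k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            b * h * w, c * k * k
        )
        self._cols = cols
        self._xshape = x.shape
        out = cols @ self.W.reshape(self.W.shape[0], -1).T + self.b
        return out.reshape(b, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout):
        k = self.k
        b, c, h, w = self._xshape
        o = self.W.shape[0]
        dflat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(b * h * w, o)
        self.dW = (dflat.T @ self._cols).reshape(self.W.shape)
        self.db = dflat.sum(axis=0)
        dcols = (dflat @ self.W.reshape(o, -1)).reshape(b, h, w, c, k, k)
        pl, pr = (k - 1) // 2, k // 2
        dxp = np.zeros((b, c, h + pl + pr, w + pl + pr))
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di : di + h, dj : dj + w] += dcols[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2
                )
        self._cols = None
        return dxp[:, :, pl : pl + h, pr : pr + w]

    @property
    def grads(self):
        return [self.dW, self.db]


class ReLU:
    params = []
    grads = []

    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    params = []
    grads = []

    def forward(self, x, train=False):
        b, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, : 2 * h2, : 2 * w2].reshape(b, c, h2, 2, w2, 2)
        out = xc.max(axis=(3, 5))
        self._x = x
        self._out = out
        return out

    def backward(self, dout):
        x = self._x
        b, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, : 2 * h2, : 2 * w2].reshape(b, c, h2, 2, w2, 2)
        mask = xc == self._out[:, :, :, None, :, None]
        # split ties evenly so the gradient stays correct
        mask = mask / mask.sum(axis=(3, 5), keepdims=True)
        dx = np.zeros_like(x)
        dx[:, :, : 2 * h2, : 2 * w2] = (
            mask * dout[:, :, :, None, :, None]
        ).reshape(b, c, 2 * h2, 2 * w2)
        self._x = None
        return dx


class Flatten:
    params = []
    grads = []

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.b = np.zeros(n_out)

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        self._x = None
        return dout @ self.W.T

    @property
    def grads(self):
        return [self.dW, self.db]


class Dropout:
    """Inverted dropout: active only in training; identity at inference."""

    params = []
    grads = []

    def __init__(self, keep: float, rng: np.random.Generator):
        if not (0 < keep <= 1):
            raise ValueError("keep probability must be in (0, 1]")
        self.keep = keep
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.keep >= 1.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) < self.keep) / self.keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class Network:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self):
        return [p for layer in self.layers for p in layer.params]

    def gradients(self):
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def get_weights(self):
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights):
        for p, w in zip(self.parameters(), weights):
            p[...] = w


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    return float(-np.log(np.maximum(probs[np.arange(y.size), y], 1e-12)).mean())


def build_lenet(
    input_shape,
    conv_filters=(64, 96),
    dense_units=(120, 84),
    n_classes: int = 2,
    dropout_keep: float = 0.8,
    seed: int = 0,
) -> Network:
    """Build the LeNet variant for a (C, H, W) input."""
    c, h, w = input_shape
    if h < 4 or w < 4:
        raise ValueError(f"input {h}x{w} too small (need at least 4x4)")
    k = 5 if h >= 20 else 3
    rng = np.random.default_rng(seed)
    layers = []
    ch = c
    for f in conv_filters:
        layers.append(Conv2D(ch, f, k, rng))
        layers.append(ReLU())
        if h // 2 >= 1 and w // 2 >= 1:
            layers.append(MaxPool2())
            h, w = h // 2, w // 2
        ch = f
    layers.append(Flatten())
    n_in = ch * h * w
    for u in dense_units:
        layers.append(Dense(n_in, u, rng))
        layers.append(Dropout(dropout_keep, rng))
        layers.append(ReLU())
        n_in = u
    layers.append(Dense(n_in, n_classes, rng))
    return Network(layers)


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class LeNetClassifier(BaseEstimator, ClassifierMixin):
    """Two-class CNN classifier over (n, C, H, W) tensors.

    Parameters follow the training regime used throughout the package:
    Adam at ``learning_rate`` 1e-3, batches of 16, up to ``epochs``
    passes with optional early stopping (patience on the monitored loss,
    best weights restored).  With ``validation_fraction`` > 0 the
    monitored loss is computed on a stratified held-out split of the
    training data; otherwise the training loss is monitored.
    """

    def __init__(
        self,
        epochs: int = 100,
        batch_size: int = 16,
        learning_rate: float = 1e-3,
        dropout_keep: float = 0.8,
        early_stopping_patience: int | None = 15,
        validation_fraction: float = 0.0,
        conv_filters=(64, 96),
        dense_units=(120, 84),
        seed: int = 0,
    ):
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.dropout_keep = dropout_keep
        self.early_stopping_patience = early_stopping_patience
        self.validation_fraction = validation_fraction
        self.conv_filters = conv_filters
        self.dense_units = dense_units
        self.seed = seed

    def fit(self, X, y):
        x = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if x.ndim != 4:
            raise ValueError(f"X must be (n, C, H, W), got {x.shape}")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training set contains a single class")
        self.classes_ = np.array([0, 1])

        rng = np.random.default_rng(self.seed)
        self.network_ = build_lenet(
            x.shape[1:],
            conv_filters=tuple(self.conv_filters),
            dense_units=tuple(self.dense_units),
            dropout_keep=self.dropout_keep,
            seed=self.seed,
        )
        opt = Adam(self.network_.parameters(), lr=self.learning_rate)

        # optional stratified validation split for early stopping
        idx = np.arange(x.shape[0])
        val_idx = np.array([], dtype=int)
        if self.validation_fraction > 0 and x.shape[0] >= 10:
            for c in (0, 1):
                cand = idx[y == c]
                k = max(1, int(round(self.validation_fraction * cand.size)))
                val_idx = np.concatenate([val_idx, rng.permutation(cand)[:k]])
            val_idx = np.sort(val_idx)
        train_idx = np.setdiff1d(idx, val_idx)
        xt, yt = x[train_idx], y[train_idx]
        xv, yv = x[val_idx], y[val_idx]

        best_loss, best_weights, since_best = np.inf, None, 0
        self.loss_history_ = []
        for _ in range(self.epochs):
            order = rng.permutation(xt.shape[0])
            epoch_loss = 0.0
            for lo in range(0, xt.shape[0], self.batch_size):
                b = order[lo : lo + self.batch_size]
                probs = softmax(self.network_.forward(xt[b], train=True))
                epoch_loss += cross_entropy(probs, yt[b]) * b.size
                grad = probs.copy()
                grad[np.arange(b.size), yt[b]] -= 1.0
                grad /= b.size
                self.network_.backward(grad)
                opt.step(self.network_.parameters(), self.network_.gradients())
            epoch_loss /= xt.shape[0]
            self.loss_history_.append(epoch_loss)

            if self.early_stopping_patience is not None:
                if val_idx.size:
                    monitored = cross_entropy(
                        softmax(self.network_.forward(xv, train=False)), yv
                    )
                else:
                    monitored = epoch_loss
                if monitored < best_loss - 1e-6:
                    best_loss, since_best = monitored, 0
                    best_weights = self.network_.get_weights()
                else:
                    since_best += 1
                    if since_best >= self.early_stopping_patience:
                        break
        if best_weights is not None:
            self.network_.set_weights(best_weights)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "network_")
        x = np.asarray(X, dtype=float)
        return softmax(self.network_.forward(x, train=False))

    def predict(self, X):
        probs = self.predict_proba(X)
        return probs.argmax(axis=1)  # argmax takes the first max: ties -> control (0)
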