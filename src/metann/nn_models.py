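"""Restricted MLP and 1D-CNN classifiers for normalized abundance features.

Both networks are deliberately small — two to three hidden layers for the
MLP, two conv/pool stages for the CNN — because microbial datasets have few
samples relative to features and larger nets over-fit. Training minimizes the
softmax cross-entropy with the Adam optimizer for a *fixed* number of epochs
(100 for the MLP, 200 for the CNN); there is no early stopping, the fixed
budget itself being the over-fitting guard. Dropout is applied at the input
layer of the MLP and after the first convolution of the CNN, in training mode
only, using the inverted convention (survivors scaled by 1/(1-q)) so that
evaluation needs no rescaling.

The whole stack (layers, backprop, Adam) is implemented here on numpy; every
source of randomness — weight initialization, mini-batch shuffling, dropout
masks — flows from the generator handed to the train functions, so a fixed
seed reproduces the final weights bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .preprocess import AbundanceMatrix

__all__ = [
    "MLPSpec",
    "CNNSpec",
    "TrainedModel",
    "softmax",
    "cross_entropy_loss",
    "apply_input_dropout",
    "phylo_sort",
    "default_hidden_sizes",
    "train_mlp",
    "train_cnn",
    "predict_proba",
    "predict",
]


class NNError(ValueError):
    pass


# ---------------------------------------------------------------------------
# functional pieces


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax exp(z_i)/sum_l exp(z_l), max-subtracted for stability."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise NNError("softmax of an empty vector is undefined")
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Summed cross entropy J = -sum_i log p_i[y_i] over the batch."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if probs.ndim != 2:
        raise NNError("probs must be a 2-D (N x K) matrix")
    n, k = probs.shape
    if labels.shape != (n,):
        raise NNError("labels must be a vector of length N")
    if labels.min() < 0 or labels.max() >= k:
        raise NNError("label index outside [0, K)")
    picked = probs[np.arange(n), labels]
    return float(-np.sum(np.log(np.maximum(picked, 1e-300))))


def apply_input_dropout(
    features: np.ndarray,
    q: float,
    rng: np.random.Generator,
    training: bool = True,
) -> np.ndarray:
    """Zero each unit independently with probability ``q`` during training.

    Survivors are scaled by 1/(1-q) (inverted dropout); in evaluation mode the
    input is returned unchanged.
    """
    if not 0.0 <= q < 1.0:
        raise NNError("dropout rate q must lie in [0, 1)")
    features = np.asarray(features, dtype=float)
    if not training or q == 0.0:
        return features
    mask = rng.random(features.shape) >= q
    return features * mask / (1.0 - q)


def phylo_sort(
    otu_ids: Sequence[str], taxonomy: Mapping[str, str] | None
) -> np.ndarray:
    """Permutation ordering OTUs by their concatenated taxonomy strings.

    Annotated OTUs sort lexicographically by taxonomy (stable: ties keep their
    original relative order); OTUs without an annotation follow, alphabetically
    by OTU id. With no taxonomy at all the identity permutation is returned, so
    phylogenetically related taxa end up adjacent whenever annotations exist.
    """
    if not taxonomy:
        return np.arange(len(otu_ids))

    def key(item):
        idx, oid = item
        tax = taxonomy.get(oid)
        if tax is None:
            return (1, oid, idx)
        return (0, tax, idx)

    order = sorted(enumerate(otu_ids), key=key)
    return np.asarray([idx for idx, _ in order])


def default_hidden_sizes(n_features: int, depth: int = 2) -> tuple[int, ...]:
    """Hidden-width rule: nearest power of two >= feature count, then halving."""
    if n_features < 1:
        raise NNError("need at least one feature")
    first = 1 << max(int(np.ceil(np.log2(max(n_features, 2)))), 1)
    return tuple(max(first >> i, 2) for i in range(depth))


# ---------------------------------------------------------------------------
# layers (manual backprop)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(n_in)
        self.W = rng.uniform(-bound, bound, size=(n_in, n_out))
        self.b = rng.uniform(-bound, bound, size=n_out)

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.dW = self._x.T @ g
        self.db = g.sum(axis=0)
        return g @ self.W.T

    def params(self):
        return [("W", self), ("b", self)]


class _ReLU:
    def forward(self, x, training, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask

    def params(self):
        return []


class _Dropout:
    def __init__(self, q: float):
        if not 0.0 <= q < 1.0:
            raise NNError("dropout rate q must lie in [0, 1)")
        self.q = q

    def forward(self, x, training, rng):
        if not training or self.q == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.q) / (1.0 - self.q)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask

    def params(self):
        return []


class _Conv1D:
    """Same-padding 1-D convolution: (N, C_in, P) -> (N, C_out, P)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        bound = 1.0 / np.sqrt(c_in * kernel)
        self.W = rng.uniform(-bound, bound, size=(c_in * kernel, c_out))
        self.b = rng.uniform(-bound, bound, size=c_out)

    def _im2col(self, x):
        n, c, p = x.shape
        pad = self.k // 2
        xp = np.zeros((n, c, p + 2 * pad))
        xp[:, :, pad:pad + p] = x
        cols = np.empty((n, p, c * self.k))
        for ci in range(c):
            for o in range(self.k):
                cols[:, :, ci * self.k + o] = xp[:, ci, o:o + p]
        return cols

    def forward(self, x, training, rng):
        self._shape = x.shape
        self._cols = self._im2col(x)
        out = self._cols @ self.W + self.b  # (N, P, C_out)
        return out.transpose(0, 2, 1)

    def backward(self, g):
        n, c, p = self._shape
        gt = g.transpose(0, 2, 1)  # (N, P, C_out)
        flat_cols = self._cols.reshape(-1, self.c_in * self.k)
        flat_g = gt.reshape(-1, self.c_out)
        self.dW = flat_cols.T @ flat_g
        self.db = flat_g.sum(axis=0)
        dcols = gt @ self.W.T  # (N, P, C_in*k)
        pad = self.k // 2
        dxp = np.zeros((n, c, p + 2 * pad))
        for ci in range(c):
            for o in range(self.k):
                dxp[:, ci, o:o + p] += dcols[:, :, ci * self.k + o]
        return dxp[:, :, pad:pad + p]

    def params(self):
        return [("W", self), ("b", self)]


class _MaxPool1D:
    """Kernel-2 stride-2 max pooling with floor division (tail dropped)."""

    def forward(self, x, training, rng):
        n, c, p = x.shape
        self._shape = x.shape
        po = p // 2
        trimmed = x[:, :, : 2 * po].reshape(n, c, po, 2)
        self._argmax = trimmed.argmax(axis=-1)
        return trimmed.max(axis=-1)

    def backward(self, g):
        n, c, p = self._shape
        po = p // 2
        dx = np.zeros((n, c, po, 2))
        idx = np.indices((n, c, po))
        dx[idx[0], idx[1], idx[2], self._argmax] = g
        out = np.zeros((n, c, p))
        out[:, :, : 2 * po] = dx.reshape(n, c, 2 * po)
        return out

    def params(self):
        return []


class _Flatten:
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)

    def params(self):
        return []


class _Reshape1D:
    """(N, P) -> (N, 1, P) so dense features enter the conv stack."""

    def forward(self, x, training, rng):
        return x[:, None, :]

    def backward(self, g):
        return g[:, 0, :]

    def params(self):
        return []


class _Adam:
    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.slots = []
        for layer in layers:
            for name, owner in layer.params():
                p = getattr(owner, name)
                self.slots.append(
                    (owner, name, np.zeros_like(p), np.zeros_like(p))
                )

    def step(self):
        self.t += 1
        for owner, name, m, v in self.slots:
            g = getattr(owner, "d" + name)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p = getattr(owner, name)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# specs and models


@dataclass
class MLPSpec:
    """Restricted multilayer perceptron: 2-3 rectifier hidden layers.

    ``hidden_sizes=None`` applies :func:`default_hidden_sizes` at fit time.
    ``input_dropout_q`` is the input-unit drop rate (0 disables dropout).
    """

    hidden_sizes: Sequence[int] | None = None
    input_dropout_q: float = 0.0
    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 32

    def resolve_hidden(self, n_features: int) -> tuple[int, ...]:
        sizes = (
            tuple(int(h) for h in self.hidden_sizes)
            if self.hidden_sizes is not None
            else default_hidden_sizes(n_features)
        )
        if not 2 <= len(sizes) <= 3:
            raise NNError("MLP must have two or three hidden layers")
        if any(h < 1 for h in sizes):
            raise NNError("hidden sizes must be positive")
        return sizes


@dataclass
class CNNSpec:
    """Two-stage 1-D conv net: Conv1D(L,K) -> Dropout -> ReLU -> MaxPool(2)
    -> Conv1D(L,K) -> ReLU -> MaxPool(2) -> FC, on taxonomy-ordered features.
    """

    channels: int = 8
    kernel_size: int = 3
    dropout_q: float = 0.0
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 32


@dataclass
class TrainedModel:
    kind: str
    spec: object
    layers: list
    classes: np.ndarray
    n_features: int
    feature_ordering: np.ndarray | None = None
    loss_trace: list = field(default_factory=list)


def _as_array(features) -> np.ndarray:
    if isinstance(features, AbundanceMatrix):
        return features.values
    return np.asarray(features, dtype=float)


def _encode_labels(labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise NNError("training requires at least two classes")
    lookup = {c: i for i, c in enumerate(classes)}
    return classes, np.asarray([lookup[v] for v in labels])


def _forward(layers, x, training, rng):
    for layer in layers:
        x = layer.forward(x, training, rng)
    return x


def _fit(layers, x, y_idx, n_classes, epochs, lr, batch_size, rng):
    n = x.shape[0]
    if n < batch_size:  # full batch for tiny training sets
        batch_size = n
    opt = _Adam(layers, lr=lr)
    trace = []
    for _ in range(epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            sel = perm[start:start + batch_size]
            xb, yb = x[sel], y_idx[sel]
            logits = _forward(layers, xb, True, rng)
            probs = softmax(logits)
            epoch_loss += cross_entropy_loss(probs, yb)
            grad = probs.copy()
            grad[np.arange(len(yb)), yb] -= 1.0
            grad /= len(yb)
            for layer in reversed(layers):
                grad = layer.backward(grad)
            opt.step()
        trace.append(epoch_loss / n)
    return trace


def train_mlp(
    features, labels, spec: MLPSpec | None = None, rng: np.random.Generator | None = None
) -> TrainedModel:
    """Train the restricted MLP for exactly ``spec.epochs`` epochs with Adam."""
    if spec is None:
        spec = MLPSpec()
    if rng is None:
        rng = np.random.default_rng(0)
    x = _as_array(features)
    classes, y_idx = _encode_labels(labels)
    hidden = spec.resolve_hidden(x.shape[1])
    layers: list = [_Dropout(spec.input_dropout_q)]
    widths = [x.shape[1], *hidden]
    for n_in, n_out in zip(widths[:-1], widths[1:]):
        layers += [_Dense(n_in, n_out, rng), _ReLU()]
    layers.append(_Dense(widths[-1], classes.size, rng))
    trace = _fit(layers, x, y_idx, classes.size, spec.epochs,
                 spec.learning_rate, spec.batch_size, rng)
    return TrainedModel("mlp", spec, layers, classes, x.shape[1], None, trace)


def train_cnn(
    features,
    labels,
    ordering: np.ndarray | None = None,
    spec: CNNSpec | None = None,
    rng: np.random.Generator | None = None,
) -> TrainedModel:
    """Train the 1-D CNN on features re-ordered by ``ordering``.

    Convolutions are same-padded, pooling floors odd lengths, so the flattened
    feature length is floor(floor(P/2)/2) * channels — about P/4 per channel.
    """
    if spec is None:
        spec = CNNSpec()
    if rng is None:
        rng = np.random.default_rng(0)
    x = _as_array(features)
    p = x.shape[1]
    if p < 4:
        raise NNError("CNN needs at least 4 features for two pooling stages")
    if ordering is None:
        ordering = np.arange(p)
    ordering = np.asarray(ordering)
    if sorted(ordering.tolist()) != list(range(p)):
        raise NNError("ordering must be a permutation of the feature indices")
    classes, y_idx = _encode_labels(labels)
    x = x[:, ordering]
    flat = (p // 2 // 2) * spec.channels
    layers: list = [
        _Reshape1D(),
        _Conv1D(1, spec.channels, spec.kernel_size, rng),
        _Dropout(spec.dropout_q),
        _ReLU(),
        _MaxPool1D(),
        _Conv1D(spec.channels, spec.channels, spec.kernel_size, rng),
        _ReLU(),
        _MaxPool1D(),
        _Flatten(),
        _Dense(flat, classes.size, rng),
    ]
    trace = _fit(layers, x, y_idx, classes.size, spec.epochs,
                 spec.learning_rate, spec.batch_size, rng)
    return TrainedModel("cnn", spec, layers, classes, p, ordering, trace)


def predict_proba(model: TrainedModel, features) -> np.ndarray:
    """Class-probability matrix (rows sum to 1); dropout disabled."""
    x = _as_array(features)
    if x.shape[1] != model.n_features:
        raise NNError(
            f"model expects {model.n_features} features, got {x.shape[1]}"
        )
    if model.feature_ordering is not None:
        x = x[:, model.feature_ordering]
    logits = _forward(model.layers, x, False, None)
    return softmax(logits)


def predict(model: TrainedModel, features) -> np.ndarray:
    """Predicted labels: argmax of the class probabilities."""
    probs = predict_proba(model, features)
    return model.classes[np.argmax(probs, axis=1)]
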