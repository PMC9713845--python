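"""Per-participant deep classifiers for next-day adherence.

Three small architectures map a (window_size x 4) block of normalized daily
predictors to the probability that the next day meets the minimal adherence
criterion:

* **cnn** -- two blocks of 1-D valid convolution (64 filters, kernel 2) and
  max pooling (pool 2), then flatten, a 32-unit dense layer and a sigmoid
  output;
* **lstm** -- a single 32-unit LSTM consuming the window day by day, then a
  32-unit dense layer and a sigmoid output;
* **cnn_lstm** -- the window is cut into two contiguous subsequences, each
  encoded by a shared Conv(32, kernel 2) + MaxPool(2) + flatten block, and
  the two encodings are consumed in order by a 32-unit LSTM with a sigmoid
  output.

The layers, backpropagation and the Adam optimizer are implemented directly
on numpy arrays; gradients are validated against finite differences in the
test suite. Training minimizes binary cross-entropy and is deterministic
given the training seed. Windows are short (2-10 days) and training sets
small (tens to a few hundred samples), so exact full-precision batched
backprop is fast and dependency-free.

Degenerate shapes are handled so every family accepts the whole window-size
clamp range: a pooling stage whose floor-divided output length would be zero
becomes a no-op, and a convolution whose input is shorter than its kernel
clamps the kernel to the input length.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .windowing import WindowSample

__all__ = [
    "ArchitectureSpec",
    "TrainingConfig",
    "TrainedPredictor",
    "ModelError",
    "FAMILIES",
    "build_model",
    "train",
    "predict_proba",
    "predict_label",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

FAMILIES = ("cnn", "lstm", "cnn_lstm")

_PROB_EPS = 1e-7  # keeps probabilities strictly inside (0, 1)


class ModelError(ValueError):
    """Invalid architecture specification or input shape."""


@dataclass(frozen=True)
class ArchitectureSpec:
    """Hyperparameters of one classifier family.

    ``conv_filters`` defaults depend on the family (64 for cnn, 32 for
    cnn_lstm); use :func:`default_spec` to get the canonical per-family spec.
    """

    family: str
    window_size: int
    n_features: int = 4
    conv_filters: int = 64
    kernel_size: int = 2
    pool_size: int = 2
    dense_units: int = 32
    lstm_units: int = 32

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ModelError(f"unknown family {self.family!r}")
        if self.window_size < 2:
            raise ModelError("window_size must be at least 2")
        if min(self.n_features, self.conv_filters, self.kernel_size,
               self.pool_size, self.dense_units, self.lstm_units) < 1:
            raise ModelError("all architecture dimensions must be positive")
        if self.family == "cnn" and self.window_size < self.kernel_size:
            raise ModelError("cnn window_size must be >= kernel_size")


def default_spec(family: str, window_size: int, n_features: int = 4) -> ArchitectureSpec:
    """Canonical spec per family: cnn uses 64 conv filters, cnn_lstm 32."""
    filters = 32 if family == "cnn_lstm" else 64
    return ArchitectureSpec(
        family=family,
        window_size=window_size,
        n_features=n_features,
        conv_filters=filters,
    )


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings: Adam on binary cross-entropy."""

    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    epochs: int = 100
    batch_size: int = 16
    decision_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ModelError("epochs must be at least 1")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ModelError("decision_threshold must lie in (0, 1)")
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ModelError("learning_rate and batch_size must be positive")
        if self.weight_decay < 0:
            raise ModelError("weight_decay must be non-negative")


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------

class _Layer:
    """Minimal layer protocol: forward caches, backward accumulates grads."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class _Conv1D(_Layer):
    """Valid-mode stride-1 1-D convolution with ReLU.

    Input (B, L, C) -> output (B, L - k + 1, F) where the kernel length k is
    clamped to L when the input is shorter than the nominal kernel.
    """

    def __init__(self, c_in: int, filters: int, kernel: int, length_in: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.k = min(kernel, length_in)
        self.length_out = length_in - self.k + 1
        limit = math.sqrt(6.0 / (self.k * c_in + filters))
        self.params = {
            "W": rng.uniform(-limit, limit, size=(self.k, c_in, filters)),
            "b": np.zeros(filters),
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        W, b = self.params["W"], self.params["b"]
        y = np.zeros((x.shape[0], self.length_out, W.shape[2]))
        for j in range(self.k):
            y += x[:, j : j + self.length_out, :] @ W[j]
        y += b
        self._x = x
        self._mask = y > 0
        return y * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = dy * self._mask
        W = self.params["W"]
        dW = np.zeros_like(W)
        dx = np.zeros_like(self._x)
        for j in range(self.k):
            xs = self._x[:, j : j + self.length_out, :]
            dW[j] = np.einsum("bic,bif->cf", xs, dy)
            dx[:, j : j + self.length_out, :] += dy @ W[j].T
        self.grads = {"W": dW, "b": dy.sum(axis=(0, 1))}
        return dx


class _MaxPool1D(_Layer):
    """Non-overlapping max pooling; a no-op when the floored length is zero."""

    def __init__(self, pool: int, length_in: int) -> None:
        super().__init__()
        self.pool = pool
        self.noop = length_in // pool == 0
        self.length_out = length_in if self.noop else length_in // pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.noop:
            return x
        B, L, C = x.shape
        Lo = self.length_out
        blocks = x[:, : Lo * self.pool, :].reshape(B, Lo, self.pool, C)
        self._arg = blocks.argmax(axis=2)
        self._shape = x.shape
        return blocks.max(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.noop:
            return dy
        B, Lo, C = dy.shape
        dblocks = np.zeros((B, Lo, self.pool, C))
        np.put_along_axis(dblocks, self._arg[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros(self._shape)
        dx[:, : Lo * self.pool, :] = dblocks.reshape(B, Lo * self.pool, C)
        return dx


class _Flatten(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class _Dense(_Layer):
    """Fully connected layer with relu, sigmoid, or linear activation."""

    def __init__(self, n_in: int, n_out: int, activation: str,
                 rng: np.random.Generator) -> None:
        super().__init__()
        limit = math.sqrt(6.0 / (n_in + n_out))
        self.params = {
            "W": rng.uniform(-limit, limit, size=(n_in, n_out)),
            "b": np.zeros(n_out),
        }
        self.activation = activation

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            self._mask = z > 0
            return z * self._mask
        if self.activation == "sigmoid":
            self._y = 1.0 / (1.0 + np.exp(-z))
            return self._y
        return z

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            dz = dy * self._mask
        elif self.activation == "sigmoid":
            dz = dy * self._y * (1.0 - self._y)
        else:
            dz = dy
        self.grads = {"W": self._x.T @ dz, "b": dz.sum(axis=0)}
        return dz @ self.params["W"].T


class _LSTM(_Layer):
    """Single LSTM layer returning the final hidden state.

    Gate order in the packed weight matrix is (input, forget, output,
    candidate); the forget-gate bias starts at 1 so early training does not
    erase the cell state.
    """

    def __init__(self, c_in: int, units: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.units = units
        limit = math.sqrt(6.0 / (c_in + units + 4 * units))
        b = np.zeros(4 * units)
        b[units : 2 * units] = 1.0
        self.params = {
            "W": rng.uniform(-limit, limit, size=(c_in + units, 4 * units)),
            "b": b,
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        U = self.units
        W, b = self.params["W"], self.params["b"]
        h = np.zeros((B, U))
        c = np.zeros((B, U))
        self._x = x
        self._cache = []
        for t in range(T):
            xh = np.concatenate([x[:, t, :], h], axis=1)
            z = xh @ W + b
            i = _sigmoid(z[:, :U])
            f = _sigmoid(z[:, U : 2 * U])
            o = _sigmoid(z[:, 2 * U : 3 * U])
            g = np.tanh(z[:, 3 * U :])
            c_prev = c
            c = f * c_prev + i * g
            h = o * np.tanh(c)
            self._cache.append((xh, i, f, o, g, c_prev, c))
        return h

    def backward(self, dh_last: np.ndarray) -> np.ndarray:
        W = self.params["W"]
        U = self.units
        D = self._x.shape[2]
        dW = np.zeros_like(W)
        db = np.zeros_like(self.params["b"])
        dx = np.zeros_like(self._x)
        dh = dh_last
        dc = np.zeros_like(dh_last)
        for t in range(len(self._cache) - 1, -1, -1):
            xh, i, f, o, g, c_prev, c = self._cache[t]
            tc = np.tanh(c)
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    do * o * (1.0 - o),
                    dg * (1.0 - g * g),
                ],
                axis=1,
            )
            dW += xh.T @ dz
            db += dz.sum(axis=0)
            dxh = dz @ W.T
            dx[:, t, :] = dxh[:, :D]
            dh = dxh[:, -U:]
            dc = dc * f
        self.grads = {"W": dW, "b": db}
        return dx


class _TimeDistributed(_Layer):
    """Apply a shared stack of layers independently to each subsequence.

    Input (B, S, L, C) is folded to (B*S, L, C), run through the inner
    layers, and unfolded to (B, S, features).
    """

    def __init__(self, layers: list[_Layer]) -> None:
        super().__init__()
        self.layers = layers

    @property
    def sublayers(self) -> list[_Layer]:
        return self.layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, S = x.shape[:2]
        y = x.reshape(B * S, *x.shape[2:])
        for layer in self.layers:
            y = layer.forward(y)
        self._bs = (B, S)
        return y.reshape(B, S, -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, S = self._bs
        d = dy.reshape(B * S, -1)
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d.reshape(B, S, *d.shape[1:])


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _iter_param_layers(layers: Sequence[_Layer]):
    for layer in layers:
        if isinstance(layer, _TimeDistributed):
            yield from _iter_param_layers(layer.sublayers)
        elif layer.params:
            yield layer


class _Adam:
    """Adam with bias-corrected moments and decoupled weight decay.

    Decay applies to weight matrices only, never biases.
    """

    def __init__(self, lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m: dict[int, dict[str, np.ndarray]] = {}
        self.v: dict[int, dict[str, np.ndarray]] = {}

    def step(self, layers: Sequence[_Layer]) -> None:
        self.t += 1
        for lid, layer in enumerate(_iter_param_layers(layers)):
            m = self.m.setdefault(lid, {k: np.zeros_like(v) for k, v in layer.params.items()})
            v = self.v.setdefault(lid, {k: np.zeros_like(p) for k, p in layer.params.items()})
            for key, grad in layer.grads.items():
                m[key] = self.beta1 * m[key] + (1 - self.beta1) * grad
                v[key] = self.beta2 * v[key] + (1 - self.beta2) * grad * grad
                mhat = m[key] / (1 - self.beta1 ** self.t)
                vhat = v[key] / (1 - self.beta2 ** self.t)
                update = mhat / (np.sqrt(vhat) + self.eps)
                if self.weight_decay and key != "b":
                    update = update + self.weight_decay * layer.params[key]
                layer.params[key] -= self.lr * update


# --------------------------------------------------------------------------
# architectures
# --------------------------------------------------------------------------

def _subsequence_shape(window_size: int) -> tuple[int, int]:
    """(n_subsequences, subsequence_length) for the hybrid encoder.

    Windows of at least 4 days split into 2 contiguous halves (the second
    edge-padded when the window is odd); shorter windows stay whole.
    """
    if window_size < 4:
        return 1, window_size
    return 2, math.ceil(window_size / 2)


def split_subsequences(x: np.ndarray, window_size: int) -> np.ndarray:
    """(B, w, C) -> (B, S, L, C) contiguous split with edge-repeat padding."""
    n_sub, sub_len = _subsequence_shape(window_size)
    if n_sub == 1:
        return x[:, None, :, :]
    first = x[:, :sub_len, :]
    second = x[:, sub_len:, :]
    deficit = sub_len - second.shape[1]
    if deficit:
        pad = np.repeat(second[:, -1:, :], deficit, axis=1)
        second = np.concatenate([second, pad], axis=1)
    return np.stack([first, second], axis=1)


@dataclass
class TrainedPredictor:
    """A (possibly untrained) classifier: architecture, parameters, history."""

    spec: ArchitectureSpec
    layers: list[_Layer] = field(repr=False)
    training_history: list[float] = field(default_factory=list)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.spec.family == "cnn_lstm":
            x = split_subsequences(x, self.spec.window_size)
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> None:
        d = dy
        for layer in reversed(self.layers):
            d = layer.backward(d)


def build_model(spec: ArchitectureSpec, seed: int = 0) -> TrainedPredictor:
    """Instantiate an untrained classifier with seeded initial parameters."""
    rng = np.random.Generator(np.random.PCG64(seed))
    w, nf = spec.window_size, spec.n_features
    layers: list[_Layer] = []
    if spec.family == "cnn":
        L = w
        conv1 = _Conv1D(nf, spec.conv_filters, spec.kernel_size, L, rng)
        L = conv1.length_out
        pool1 = _MaxPool1D(spec.pool_size, L)
        L = pool1.length_out
        conv2 = _Conv1D(spec.conv_filters, spec.conv_filters, spec.kernel_size, L, rng)
        L = conv2.length_out
        pool2 = _MaxPool1D(spec.pool_size, L)
        L = pool2.length_out
        layers = [
            conv1, pool1, conv2, pool2, _Flatten(),
            _Dense(L * spec.conv_filters, spec.dense_units, "relu", rng),
            _Dense(spec.dense_units, 1, "sigmoid", rng),
        ]
    elif spec.family == "lstm":
        layers = [
            _LSTM(nf, spec.lstm_units, rng),
            _Dense(spec.lstm_units, spec.dense_units, "relu", rng),
            _Dense(spec.dense_units, 1, "sigmoid", rng),
        ]
    else:  # cnn_lstm
        _, sub_len = _subsequence_shape(w)
        conv = _Conv1D(nf, spec.conv_filters, spec.kernel_size, sub_len, rng)
        L = conv.length_out
        pool = _MaxPool1D(spec.pool_size, L)
        L = pool.length_out
        encoder = _TimeDistributed([conv, pool, _Flatten()])
        layers = [
            encoder,
            _LSTM(L * spec.conv_filters, spec.lstm_units, rng),
            _Dense(spec.lstm_units, 1, "sigmoid", rng),
        ]
    return TrainedPredictor(spec=spec, layers=layers)


# --------------------------------------------------------------------------
# training and inference
# --------------------------------------------------------------------------

def _stack_samples(samples: Sequence[WindowSample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([s.features for s in samples]).astype(float)
    y = np.array([s.label for s in samples], dtype=float)
    return X, y


def train(
    model: TrainedPredictor,
    train_samples: Sequence[WindowSample],
    config: TrainingConfig = TrainingConfig(),
) -> TrainedPredictor:
    """Fit the classifier by Adam on binary cross-entropy.

    One history entry (mean training loss) per epoch. Shuffling is seeded, so
    repeated runs with the same model seed and config are identical. Training
    proceeds on single-class labels but logs a degeneracy warning, since the
    predictions will collapse toward the lone class.
    """
    if not train_samples:
        raise ModelError("train_samples must be non-empty")
    X, y = _stack_samples(train_samples)
    if X.shape[1] != model.spec.window_size or X.shape[2] != model.spec.n_features:
        raise ModelError(
            f"sample shape {X.shape[1:]} does not match spec "
            f"({model.spec.window_size}, {model.spec.n_features})"
        )
    if len(np.unique(y)) == 1:
        logger.warning(
            "single-class training labels (all %d): predictions will collapse "
            "toward that class", int(y[0])
        )
    rng = np.random.Generator(np.random.PCG64(config.seed))
    opt = _Adam(config.learning_rate, config.weight_decay)
    n = X.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], y[idx]
            p = np.clip(model.forward(xb)[:, 0], _PROB_EPS, 1 - _PROB_EPS)
            epoch_loss -= float(
                np.sum(yb * np.log(p) + (1 - yb) * np.log(1 - p))
            )
            # d(BCE)/dp, averaged over the batch
            dp = ((p - yb) / (p * (1 - p)))[:, None] / len(idx)
            model.backward(dp)
            opt.step(model.layers)
        model.training_history.append(epoch_loss / n)
    return model


def predict_proba(model: TrainedPredictor, window: np.ndarray) -> np.ndarray:
    """Next-day adherence probabilities for one window or a batch of windows."""
    x = np.asarray(window, dtype=float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    if x.shape[1] != model.spec.window_size or x.shape[2] != model.spec.n_features:
        raise ModelError(
            f"window shape {x.shape[1:]} does not match spec "
            f"({model.spec.window_size}, {model.spec.n_features})"
        )
    p = np.clip(model.forward(x)[:, 0], _PROB_EPS, 1 - _PROB_EPS)
    return p[0] if squeeze else p


def predict_label(
    model: TrainedPredictor, window: np.ndarray, threshold: float = 0.5
) -> np.ndarray:
    """1 iff the predicted probability is at or above the threshold."""
    return (np.asarray(predict_proba(model, window)) >= threshold).astype(int)


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def save_model(model: TrainedPredictor, directory: str | Path) -> None:
    """Persist parameters (.npz) and a JSON manifest of the architecture."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for lid, layer in enumerate(_iter_param_layers(model.layers)):
        for key, value in layer.params.items():
            arrays[f"layer{lid}:{key}"] = value
    np.savez(directory / "params.npz", **arrays)
    manifest = {
        "spec": model.spec.__dict__,
        "training_history": model.training_history,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_model(directory: str | Path) -> TrainedPredictor:
    """Rebuild a model from :func:`save_model` output."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    spec = ArchitectureSpec(**manifest["spec"])
    model = build_model(spec)
    model.training_history = list(manifest["training_history"])
    with np.load(directory / "params.npz") as data:
        for lid, layer in enumerate(_iter_param_layers(model.layers)):
            for key in layer.params:
                layer.params[key] = data[f"layer{lid}:{key}"]
    return model
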