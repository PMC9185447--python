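"""Feature-window neural networks (CNN, LSTM, BiLSTM, CNN-LSTM).

A compact numpy implementation (manual backpropagation, Adam) of the
four architectures compared against the classical models. The input to
every network is a single *feature window*: the vector of selected,
scaled features treated as a length-F single-channel sequence — the
recurrent nets scan across the feature vector, not across raw time.
All four end in a 20-way softmax and are trained under one fixed
regime: 100 epochs, batch size 64, Adam at a constant learning rate of
0.001, cross-entropy loss.

Architectures:

* ``cnn``: two 1-D convolution blocks (32 then 64 filters, kernel 3,
  ReLU, max-pool 2) + dense softmax;
* ``lstm``: one recurrent layer with 150 hidden units, final hidden
  state + dense softmax;
* ``bilstm``: bidirectional variant (two independent 150-unit passes,
  concatenated final states);
* ``cnn_lstm``: one convolution block feeding the recurrent layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from falladl.benchmark import EvalReport, _confusion, compute_metrics
from falladl.features import FeatureMatrix
from falladl.selection import RankingResult
from falladl.taxonomy import N_CLASSES

ARCHS = ("cnn", "lstm", "bilstm", "cnn_lstm")

# fixed training regime shared by all four architectures
DEFAULT_EPOCHS = 100
DEFAULT_BATCH = 64
DEFAULT_LR = 0.001
DEFAULT_HIDDEN = 150


@dataclass(frozen=True)
class NetSpec:
    """Architecture choice plus the (fixed) training regime."""

    arch: str
    input_width: int                    # F: number of selected features
    hidden_units: int = DEFAULT_HIDDEN
    epochs: int = DEFAULT_EPOCHS
    batch_size: int = DEFAULT_BATCH
    learning_rate: float = DEFAULT_LR
    output_width: int = N_CLASSES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arch not in ARCHS:
            raise ValueError(f"unknown architecture {self.arch!r}; options: {ARCHS}")
        if self.input_width < 1:
            raise ValueError("input_width must be >= 1")


# ---------------------------------------------------------------------------
# layers

class _Layer:
    params: dict
    grads: dict

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(_Layer):
    def __init__(self, n_in, n_out, rng):
        scale = np.sqrt(2.0 / n_in)
        self.params = {"W": rng.normal(0, scale, (n_in, n_out)), "b": np.zeros(n_out)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"][...] = self._x.T @ dy
        self.grads["b"][...] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class ReLU(_Layer):
    params: dict = {}
    grads: dict = {}

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Conv1D(_Layer):
    """Valid 1-D convolution: (B, T, Cin) -> (B, T-K+1, Cout)."""

    def __init__(self, c_in, c_out, kernel, rng):
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.params = {"W": rng.normal(0, scale, (kernel, c_in, c_out)),
                       "b": np.zeros(c_out)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.K = kernel

    def forward(self, x):
        B, T, Cin = x.shape
        K = self.K
        if T < K:
            raise ValueError(f"sequence length {T} shorter than kernel {K}")
        self._x = x
        # im2col: (B, T-K+1, K*Cin)
        cols = np.stack([x[:, k:T - K + 1 + k, :] for k in range(K)], axis=2)
        self._cols = cols.reshape(B, T - K + 1, K * Cin)
        W2 = self.params["W"].reshape(K * Cin, -1)
        return self._cols @ W2 + self.params["b"]

    def backward(self, dy):
        B, T, Cin = self._x.shape
        K = self.K
        W2 = self.params["W"].reshape(K * Cin, -1)
        self.grads["W"][...] = (
            self._cols.reshape(-1, K * Cin).T @ dy.reshape(-1, dy.shape[-1])
        ).reshape(self.params["W"].shape)
        self.grads["b"][...] = dy.sum(axis=(0, 1))
        dcols = dy @ W2.T                              # (B, T-K+1, K*Cin)
        dcols = dcols.reshape(B, T - K + 1, K, Cin)
        dx = np.zeros_like(self._x)
        for k in range(K):
            dx[:, k:T - K + 1 + k, :] += dcols[:, :, k, :]
        return dx


class MaxPool1D(_Layer):
    params: dict = {}
    grads: dict = {}

    def __init__(self, size=2):
        self.size = size

    def forward(self, x):
        B, T, C = x.shape
        s = self.size
        T2 = T // s
        if T2 < 1:
            self._passthrough = True
            return x
        self._passthrough = False
        xt = x[:, :T2 * s].reshape(B, T2, s, C)
        self._argmax = xt.argmax(axis=2)
        self._shape = x.shape
        return xt.max(axis=2)

    def backward(self, dy):
        if self._passthrough:
            return dy
        B, T, C = self._shape
        s = self.size
        T2 = T // s
        dx = np.zeros((B, T2, s, C))
        b, t, c = np.meshgrid(np.arange(B), np.arange(T2), np.arange(C), indexing="ij")
        dx[b, t, self._argmax, c] = dy
        out = np.zeros((B, T, C))
        out[:, :T2 * s] = dx.reshape(B, T2 * s, C)
        return out


class Flatten(_Layer):
    params: dict = {}
    grads: dict = {}

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))


class LSTM(_Layer):
    """Single recurrent layer; returns the final hidden state (B, H)."""

    def __init__(self, c_in, hidden, rng, reverse=False):
        H = hidden
        scale = 1.0 / np.sqrt(c_in + H)
        self.params = {
            "Wx": rng.normal(0, scale, (c_in, 4 * H)),
            "Wh": rng.normal(0, scale, (H, 4 * H)),
            "b": np.zeros(4 * H),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.H = H
        self.reverse = reverse

    def forward(self, x):
        if self.reverse:
            x = x[:, ::-1, :]
        B, T, C = x.shape
        H = self.H
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._cache = []
        self._x = x
        for t in range(T):
            z = x[:, t] @ self.params["Wx"] + h @ self.params["Wh"] + self.params["b"]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_prev = c
            c = f * c_prev + i * g
            tanh_c = np.tanh(c)
            h = o * tanh_c
            self._cache.append((i, f, g, o, c_prev, c, tanh_c, h))
        return h

    def backward(self, dh_final):
        x = self._x
        B, T, C = x.shape
        H = self.H
        for k in self.grads:
            self.grads[k][...] = 0.0
        dx = np.zeros_like(x)
        dh = dh_final.copy()
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, c, tanh_c, h = self._cache[t]
            do = dh * tanh_c
            dc = dc + dh * o * (1 - tanh_c ** 2)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc = dc * f
            dz = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - g ** 2), do * o * (1 - o),
            ], axis=1)
            h_prev = self._cache[t - 1][7] if t > 0 else np.zeros((B, H))
            self.grads["Wx"] += x[:, t].T @ dz
            self.grads["Wh"] += h_prev.T @ dz
            self.grads["b"] += dz.sum(axis=0)
            dx[:, t] = dz @ self.params["Wx"].T
            dh = dz @ self.params["Wh"].T
        if self.reverse:
            dx = dx[:, ::-1, :]
        return dx


class BiLSTM(_Layer):
    """Forward and backward passes concatenated: (B, T, C) -> (B, 2H)."""

    def __init__(self, c_in, hidden, rng):
        self.fwd = LSTM(c_in, hidden, rng)
        self.bwd = LSTM(c_in, hidden, rng, reverse=True)

    @property
    def params(self):
        return {**{f"f_{k}": v for k, v in self.fwd.params.items()},
                **{f"b_{k}": v for k, v in self.bwd.params.items()}}

    @property
    def grads(self):
        return {**{f"f_{k}": v for k, v in self.fwd.grads.items()},
                **{f"b_{k}": v for k, v in self.bwd.grads.items()}}

    def forward(self, x):
        return np.concatenate([self.fwd.forward(x), self.bwd.forward(x)], axis=1)

    def backward(self, dy):
        H = self.fwd.H
        return self.fwd.backward(dy[:, :H]) + self.bwd.backward(dy[:, H:])


# ---------------------------------------------------------------------------
# model assembly

class Model:
    """A sequential stack of layers ending in logits."""

    def __init__(self, layers, spec: NetSpec):
        self.layers = layers
        self.spec = spec

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def parameters(self):
        for li, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                yield f"{li}.{name}", p, layer.grads[name]

    def n_parameters(self) -> int:
        return sum(p.size for _, p, _ in self.parameters())

    def predict_proba(self, X: np.ndarray, batch: int = 512) -> np.ndarray:
        out = []
        for i in range(0, len(X), batch):
            logits = self.forward(_as_sequence(X[i:i + batch]))
            out.append(_softmax(logits))
        return np.vstack(out)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


def _as_sequence(X: np.ndarray) -> np.ndarray:
    """Feature matrix (B, F) -> length-F single-channel sequence (B, F, 1)."""
    return X[:, :, None]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build(spec: NetSpec) -> Model:
    """Instantiate a trainable model with seeded initial parameters."""
    rng = np.random.default_rng(spec.seed)
    H, F, K = spec.hidden_units, spec.input_width, spec.output_width
    if spec.arch == "cnn":
        layers = [
            Conv1D(1, 32, 3, rng), ReLU(), MaxPool1D(2),
            Conv1D(32, 64, 3, rng), ReLU(), MaxPool1D(2),
            Flatten(),
        ]
        t = (F - 2) // 2
        t = (t - 2) // 2
        if t < 1:
            raise ValueError(f"input width {F} too small for the cnn stack")
        layers.append(Dense(t * 64, K, rng))
    elif spec.arch == "lstm":
        layers = [LSTM(1, H, rng), Dense(H, K, rng)]
    elif spec.arch == "bilstm":
        layers = [BiLSTM(1, H, rng), Dense(2 * H, K, rng)]
    elif spec.arch == "cnn_lstm":
        layers = [Conv1D(1, 32, 3, rng), ReLU(), MaxPool1D(2),
                  LSTM(32, H, rng), Dense(H, K, rng)]
    else:  # pragma: no cover - guarded by NetSpec
        raise ValueError(spec.arch)
    return Model(layers, spec)


class Adam:
    def __init__(self, model: Model, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p) for k, p, _ in model.parameters()}
        self.v = {k: np.zeros_like(p) for k, p, _ in model.parameters()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p, g in self.model.parameters():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    return float(-np.log(np.maximum(probs[np.arange(len(y)), y], 1e-12)).mean())


def train(model: Model, X: np.ndarray, y: np.ndarray,
          verbose: bool = False) -> list[float]:
    """Train under the fixed regime; returns per-epoch mean loss."""
    spec = model.spec
    present = np.unique(y)
    if present.size < spec.output_width:
        warnings.warn(
            f"only {present.size}/{spec.output_width} classes present in "
            "training data; softmax rows for absent classes stay untrained",
            stacklevel=2)
    rng = np.random.default_rng(spec.seed + 1)
    opt = Adam(model, spec.learning_rate)
    losses = []
    n = len(X)
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, spec.batch_size):
            idx = order[i:i + spec.batch_size]
            logits = model.forward(_as_sequence(X[idx]))
            probs = _softmax(logits)
            epoch_loss += cross_entropy(probs, y[idx]) * len(idx)
            dlogits = probs.copy()
            dlogits[np.arange(len(idx)), y[idx]] -= 1.0
            model.backward(dlogits / len(idx))
            opt.step()
        losses.append(epoch_loss / n)
        if verbose and (epoch + 1) % 10 == 0:
            print(f"epoch {epoch + 1}: loss {losses[-1]:.4f}")
    return losses


def train_eval(spec: NetSpec, fm_train: FeatureMatrix, fm_test: FeatureMatrix,
               ranking: RankingResult | None = None,
               n_features: int | None = None) -> EvalReport:
    """Train on the training partition, evaluate on the test partition.

    If a ranking is given, both partitions are restricted to its top-n
    feature columns (n = ``spec.input_width`` unless overridden).
    Returns the same EvalReport schema as the classical benchmark.
    """
    import time

    if ranking is not None:
        cols = ranking.top_columns(n_features or spec.input_width)
        Xtr, Xte = fm_train.values[:, cols], fm_test.values[:, cols]
    else:
        Xtr, Xte = fm_train.values, fm_test.values
    if Xtr.shape[1] != spec.input_width:
        raise ValueError(
            f"spec.input_width={spec.input_width} but data has {Xtr.shape[1]} columns")
    model = build(spec)
    t0 = time.perf_counter()
    train(model, Xtr, np.asarray(fm_train.labels))
    t1 = time.perf_counter()
    pred = model.predict(Xte)
    t2 = time.perf_counter()
    report = compute_metrics(_confusion(np.asarray(fm_test.labels), pred,
                                        spec.output_width))
    report.train_time_s = t1 - t0
    report.test_time_s = t2 - t1
    report.test_time_per_window_s = (t2 - t1) / max(1, len(Xte))
    return report
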