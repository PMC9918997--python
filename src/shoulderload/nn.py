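"""Minimal numpy sequence-model toolkit: layers, BPTT, Adam, masked MSE.

Implements exactly what the shoulder-load regressors need: dense layers
applied per time step, bidirectional LSTM layers with full backpropagation
through time, inverted dropout, ReLU, a masked mean-squared-error loss over
padded batches of whole sequences, Adam with global-norm gradient clipping,
and seeded initialization.  Shapes are ``(batch, time, features)``
throughout; ``lengths`` gives each sequence's valid length and padded steps
are masked out of the loss (their gradients are identically zero).

The implementation favours clarity and testability over speed: gradients of
every layer are verified against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "ReLU",
    "Dropout",
    "BiLSTM",
    "Sequential",
    "Adam",
    "masked_mse",
    "pad_batch",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def pad_batch(seqs_x: list[np.ndarray], seqs_y: list[np.ndarray] | None = None):
    """Pad variable-length sequences into (B, T, F) arrays plus lengths."""
    lengths = np.array([x.shape[0] for x in seqs_x])
    T = int(lengths.max())
    B = len(seqs_x)
    X = np.zeros((B, T, seqs_x[0].shape[1]))
    for b, x in enumerate(seqs_x):
        X[b, : x.shape[0]] = x
    if seqs_y is None:
        return X, lengths
    Y = np.zeros((B, T, seqs_y[0].shape[1]))
    for b, y in enumerate(seqs_y):
        Y[b, : y.shape[0]] = y
    return X, Y, lengths


def _reverse_padded(x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each sequence within its valid length; padding stays trailing."""
    out = np.zeros_like(x)
    for b, L in enumerate(lengths):
        L = int(L)
        out[b, :L] = x[b, :L][::-1]
    return out


class Layer:
    """Base class; subclasses implement forward/backward and expose params."""

    train_mode: bool = False

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, lengths: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    """Affine map applied to the last axis (time-distributed)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        k = 1.0 / np.sqrt(n_in)
        self.W = rng.uniform(-k, k, (n_in, n_out))
        self.b = rng.uniform(-k, k, n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, lengths):
        self._x = x
        return x @ self.W + self.b

    def backward(self, gout):
        x = self._x
        self.dW[...] = np.tensordot(x, gout, axes=([0, 1], [0, 1]))
        self.db[...] = gout.sum(axis=(0, 1))
        return gout @ self.W.T


class ReLU(Layer):
    def forward(self, x, lengths):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask


class Dropout(Layer):
    """Inverted dropout; active only in training mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, lengths):
        if not self.train_mode or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, gout):
        if self._mask is None:
            return gout
        return gout * self._mask


class BiLSTM(Layer):
    """Bidirectional LSTM layer; output is the concatenation of both
    directions, width ``2 × units``.

    Both directions are evaluated in one recurrence loop: the backward
    direction runs on per-sequence-reversed input, and the two directions'
    states are stacked on a leading axis so each timestep costs a single
    batched matmul.  Gate layout is ``[i, f, o, g]`` (sigmoid gates
    contiguous).  One bias vector per gate block.
    """

    def __init__(self, n_in: int, units: int, rng: np.random.Generator):
        self.n_in, self.units = n_in, units
        k = 1.0 / np.sqrt(units)
        # leading axis = direction (0 forward, 1 backward)
        self.Wx = rng.uniform(-k, k, (2, n_in, 4 * units))
        self.Wh = rng.uniform(-k, k, (2, units, 4 * units))
        self.b = rng.uniform(-k, k, (2, 1, 4 * units))
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def grads(self):
        return [self.dWx, self.dWh, self.db]

    def forward(self, x, lengths):
        B, T, F = x.shape
        H = self.units
        self._lengths = lengths
        X = np.stack([x, _reverse_padded(x, lengths)])  # (2, B, T, F)
        self._X = X
        zx = (X.reshape(2, B * T, F) @ self.Wx).reshape(2, B, T, 4 * H) + self.b[:, None]
        h = np.zeros((2, B, H))
        c = np.zeros((2, B, H))
        gates = np.empty((2, B, T, 4 * H))
        h_prev = np.empty((2, B, T, H))
        c_prev = np.empty((2, B, T, H))
        c_all = np.empty((2, B, T, H))
        out = np.empty((2, B, T, H))
        for t in range(T):
            z = zx[:, :, t] + h @ self.Wh
            s = _sigmoid(z[:, :, : 3 * H])
            i, f, o = s[:, :, :H], s[:, :, H : 2 * H], s[:, :, 2 * H :]
            g = np.tanh(z[:, :, 3 * H :])
            h_prev[:, :, t] = h
            c_prev[:, :, t] = c
            c = f * c + i * g
            h = o * np.tanh(c)
            gates[:, :, t, : 3 * H] = s
            gates[:, :, t, 3 * H :] = g
            c_all[:, :, t] = c
            out[:, :, t] = h
        self._gates, self._h_prev, self._c_prev, self._c_all = gates, h_prev, c_prev, c_all
        return np.concatenate([out[0], _reverse_padded(out[1], lengths)], axis=2)

    def backward(self, gout):
        X = self._X
        _, B, T, F = X.shape
        H = self.units
        lengths = self._lengths
        gates, h_prev, c_prev, c_all = self._gates, self._h_prev, self._c_prev, self._c_all
        G = np.stack([gout[:, :, :H], _reverse_padded(gout[:, :, H:], lengths)])
        dz_all = np.empty((2, B, T, 4 * H))
        dh_next = np.zeros((2, B, H))
        dc_next = np.zeros((2, B, H))
        tanh_c = np.tanh(c_all)
        WhT = self.Wh.transpose(0, 2, 1)
        for t in range(T - 1, -1, -1):
            i = gates[:, :, t, :H]
            f = gates[:, :, t, H : 2 * H]
            o = gates[:, :, t, 2 * H : 3 * H]
            g = gates[:, :, t, 3 * H :]
            dh = G[:, :, t] + dh_next
            tc = tanh_c[:, :, t]
            dc = dc_next + dh * o * (1.0 - tc**2)
            dz = dz_all[:, :, t]
            dz[:, :, :H] = dc * g * i * (1 - i)
            dz[:, :, H : 2 * H] = dc * c_prev[:, :, t] * f * (1 - f)
            dz[:, :, 2 * H : 3 * H] = dh * tc * o * (1 - o)
            dz[:, :, 3 * H :] = dc * i * (1 - g**2)
            dc_next = dc * f
            dh_next = dz @ WhT
        flat_dz = dz_all.reshape(2, B * T, 4 * H)
        self.dWx[...] = X.reshape(2, B * T, F).transpose(0, 2, 1) @ flat_dz
        self.dWh[...] = h_prev.reshape(2, B * T, H).transpose(0, 2, 1) @ flat_dz
        self.db[...] = flat_dz.sum(axis=1, keepdims=True)
        dX = (flat_dz @ self.Wx.transpose(0, 2, 1)).reshape(2, B, T, F)
        return dX[0] + _reverse_padded(dX[1], lengths)


class Sequential:
    """A stack of layers with a shared train/eval mode switch."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def set_train(self, mode: bool) -> None:
        for layer in self.layers:
            layer.train_mode = mode

    def forward(self, x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, lengths)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state):
            p[...] = s


def masked_mse(pred: np.ndarray, target: np.ndarray, lengths: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over valid steps only; returns (loss, dloss/dpred)."""
    B, T, F = pred.shape
    mask = (np.arange(T)[None, :] < np.asarray(lengths)[:, None]).astype(float)[:, :, None]
    diff = (pred - target) * mask
    n = mask.sum() * F
    loss = float((diff**2).sum() / n)
    grad = 2.0 * diff / n
    return loss, grad


class Adam:
    """Adam optimizer with global-norm gradient clipping."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, clip_norm: float | None = 1.0):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g**2).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g**2
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
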