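"""Minimal NumPy neural-net engine for the shallow FM classifier.

Implements exactly the layer family the classifier needs — temporal
1-D convolution, batch normalization, ReLU, inverted dropout, dense
layers, a sigmoid/binary-cross-entropy head — together with the Adam
optimizer and an early-stopping training loop. Everything is
deterministic under an explicit ``numpy.random.Generator``; float32 is
used throughout so the matmuls stay cheap on a single CPU core.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        raise NotImplementedError


class Conv1D(Layer):
    """Temporal convolution, stride 1, no padding, spanning all channels.

    Input (N, T, C) -> output (N, T - L + 1, F). Implemented as im2col
    plus one matmul.
    """

    def __init__(self, c_in: int, n_filters: int, length: int, rng: np.random.Generator):
        fan_in = length * c_in
        self.W = (rng.standard_normal((fan_in, n_filters)) * np.sqrt(2.0 / fan_in)).astype(F32)
        self.b = np.zeros(n_filters, dtype=F32)
        self.length = length
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train, rng):
        n, t, c = x.shape
        win = sliding_window_view(x, self.length, axis=1)  # (N, T', C, L)
        cols = win.transpose(0, 1, 3, 2).reshape(n, t - self.length + 1, -1)
        self._cols = cols.astype(F32, copy=False)
        return self._cols @ self.W + self.b

    def backward(self, grad, need_dx=True):
        n, tp, f = grad.shape
        cols2 = self._cols.reshape(-1, self._cols.shape[-1])
        g2 = grad.reshape(-1, f)
        self.dW[...] = cols2.T @ g2
        self.db[...] = g2.sum(axis=0)
        return None  # first layer: input gradient never needed


class BatchNorm(Layer):
    """Per-feature normalization over the batch (and time, for 3-D input)."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n_features, dtype=F32)
        self.beta = np.zeros(n_features, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_features, dtype=F32)
        self.running_var = np.ones(n_features, dtype=F32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, train, rng):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        self._xhat = ((x - mean) * self._inv_std).astype(F32)
        self._m = int(np.prod([x.shape[i] for i in axes]))
        return self.gamma * self._xhat + self.beta

    def backward(self, grad, need_dx=True):
        axes = tuple(range(grad.ndim - 1))
        self.dgamma[...] = (grad * self._xhat).sum(axis=axes)
        self.dbeta[...] = grad.sum(axis=axes)
        m = self._m
        dxhat = grad * self.gamma
        dx = (self._inv_std / m) * (
            m * dxhat - dxhat.sum(axis=axes) - self._xhat * (dxhat * self._xhat).sum(axis=axes)
        )
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad, need_dx=True):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout: activations scaled at train time, identity at eval."""

    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, grad, need_dx=True):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad, need_dx=True):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 scale: str = "he"):
        s = np.sqrt(2.0 / n_in) if scale == "he" else np.sqrt(1.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * s).astype(F32)
        self.b = np.zeros(n_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad, need_dx=True):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T if need_dx else None


class Network:
    """A plain layer stack ending in one logit; sigmoid applied on predict."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        out = x.astype(F32, copy=False)
        for layer in self.layers:
            out = layer.forward(out, train, rng)
        return out

    def backward(self, grad: np.ndarray) -> None:
        for i, layer in enumerate(reversed(self.layers)):
            grad = layer.backward(grad, need_dx=i < len(self.layers) - 1)

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def state(self) -> list[np.ndarray]:
        snap = [p.copy() for p in self.params()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                snap += [layer.running_mean.copy(), layer.running_var.copy()]
        return snap

    def load_state(self, snap: list[np.ndarray]) -> None:
        ps = self.params()
        for p, s in zip(ps, snap[: len(ps)]):
            p[...] = s
        rest = snap[len(ps):]
        i = 0
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = rest[i]
                layer.running_var[...] = rest[i + 1]
                i += 2

    def predict_proba(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        probs = []
        dummy = np.random.default_rng(0)
        for i in range(0, len(x), batch):
            z = self.forward(x[i: i + batch], train=False, rng=dummy)
            probs.append(1.0 / (1.0 + np.exp(-z[:, 0].astype(np.float64))))
        return np.concatenate(probs) if probs else np.empty(0)


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def bce_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy from logits and its gradient wrt logits."""
    z = logits[:, 0].astype(np.float64)
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    p = 1.0 / (1.0 + np.exp(-z))
    grad = ((p - y) / len(y)).astype(F32)[:, None]
    return loss, grad


def accuracy(probs: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((probs >= 0.5) == (y >= 0.5)))


def train_early_stop(
    net: Network,
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    rng: np.random.Generator,
    batch_size: int = 32,
    patience: int = 10,
    max_epochs: int = 200,
    lr: float = 1e-3,
) -> float:
    """Mini-batch Adam with validation-accuracy early stopping.

    Training stops when validation accuracy has not improved for
    ``patience`` consecutive epochs (or at ``max_epochs``); the weights
    of the best-validation epoch are restored. Returns the best
    validation accuracy.
    """
    opt = Adam(net.params(), lr=lr)
    best_acc, best_state, since_best = -1.0, None, 0
    n = len(X)
    X = X.astype(F32, copy=False)
    for _epoch in range(max_epochs):
        order = rng.permutation(n)
        for i in range(0, n, batch_size):
            idx = order[i: i + batch_size]
            logits = net.forward(X[idx], train=True, rng=rng)
            _, grad = bce_grad(logits, y[idx])
            net.backward(grad)
            opt.step(net.grads())
        val_acc = accuracy(net.predict_proba(X_val), y_val)
        if val_acc > best_acc:
            best_acc, best_state, since_best = val_acc, net.state(), 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    if best_state is not None:
        net.load_state(best_state)
    return best_acc
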