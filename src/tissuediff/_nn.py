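"""Minimal feed-forward / 1D-convolutional network engine.

Plain-NumPy layers with explicit forward caches and manual backpropagation,
sized for the small networks used here (a ~1.3k-parameter autoencoder
classifier and a seven-convolution residual net on 9x64 windows).  Layers
default to float64; the CNN uses float32 for speed.  All stochastic elements
(initialization, dropout masks) draw from a caller-supplied
``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Linear",
    "ReLU",
    "Dropout",
    "Conv1d",
    "BatchNorm1d",
    "GlobalAvgPool1d",
    "Param",
    "Adam",
    "PlateauScheduler",
    "EarlyStopper",
    "softmax",
    "cross_entropy",
    "mse",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value)
        if self.value.dtype.kind != "f":
            self.value = self.value.astype(float)
        self.grad = np.zeros_like(self.value)


class Linear:
    """Affine map x @ W + b; He-normal init for ReLU stacks."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float64):
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(dtype))
        self.b = Param(np.zeros(n_out, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=self.W.value.dtype)
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, d):
        self.W.grad += self._x.T @ d
        self.b.grad += d.sum(axis=0)
        return d @ self.W.value.T


class ReLU:
    def params(self):
        return []

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, d):
        return d * self._mask


class Dropout:
    """Inverted dropout: active only in train mode, identity otherwise."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def params(self):
        return []

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = ((self.rng.random(x.shape) >= self.p) / (1.0 - self.p)).astype(x.dtype)
        return x * self._mask

    def backward(self, d):
        return d if self._mask is None else d * self._mask


class Conv1d:
    """1D convolution on (N, C, L) via an im2col matrix product."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None,
                 dtype=np.float64):
        if kernel < 1 or stride < 1:
            raise ValueError("kernel and stride must be positive")
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride, self.pad = kernel, stride, pad
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.W = Param(rng.normal(0.0, scale, size=(c_in * kernel, c_out)).astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    @staticmethod
    def out_length(L: int, kernel: int, stride: int, pad: int) -> int:
        return (L + 2 * pad - kernel) // stride + 1

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=self.W.value.dtype)
        N, C, L = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {C}")
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad))) if self.pad else x
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        win = win[:, :, :: self.stride, :]  # (N, C, Lout, k)
        Lout = win.shape[2]
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(
            N * Lout, C * self.kernel
        )
        self._cols, self._in_shape, self._Lout = cols, (N, C, L), Lout
        y = cols @ self.W.value + self.b.value
        return y.reshape(N, Lout, self.c_out).transpose(0, 2, 1)

    def backward(self, d):
        N, C, L = self._in_shape
        Lout = self._Lout
        dmat = np.ascontiguousarray(d.transpose(0, 2, 1)).reshape(N * Lout, self.c_out)
        self.W.grad += self._cols.T @ dmat
        self.b.grad += dmat.sum(axis=0)
        dcols = (dmat @ self.W.value.T).reshape(N, Lout, C, self.kernel)
        dcols = np.ascontiguousarray(dcols.transpose(0, 2, 3, 1))  # (N, C, k, Lout)
        dxp = np.zeros((N, C, L + 2 * self.pad), dtype=dcols.dtype)
        # scatter back; for each tap the strided targets are unique slices
        span = self.stride * (Lout - 1) + 1
        for j in range(self.kernel):
            dxp[:, :, j : j + span : self.stride] += dcols[:, :, j, :]
        return dxp[:, :, self.pad : self.pad + L] if self.pad else dxp


class BatchNorm1d:
    """Per-channel batch normalization over (N, C, L)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float64):
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mu, var = self.running_mean, self.running_var
        self._train = train
        self._ivar = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu[:, None]) * self._ivar[:, None]
        self._n = x.shape[0] * x.shape[2]
        return self.gamma.value[:, None] * self._xhat + self.beta.value[:, None]

    def backward(self, d):
        self.gamma.grad += (d * self._xhat).sum(axis=(0, 2))
        self.beta.grad += d.sum(axis=(0, 2))
        dxhat = d * self.gamma.value[:, None]
        if not self._train:
            return dxhat * self._ivar[:, None]
        n = self._n
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * self._xhat).sum(axis=(0, 2), keepdims=True)
        return (self._ivar[:, None] / n) * (n * dxhat - s1 - self._xhat * s2)


class GlobalAvgPool1d:
    def params(self):
        return []

    def forward(self, x, train=False):
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, d):
        return np.repeat(d[:, :, None], self._L, axis=2) / self._L


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Batch-mean cross-entropy; returns (loss, dloss/dlogits)."""
    if logits.shape[0] != labels.shape[0]:
        raise ValueError("logits and labels batch dimensions disagree")
    probs = softmax(logits)
    n = logits.shape[0]
    loss = -np.mean(np.log(probs[np.arange(n), labels] + 1e-300))
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def mse(prediction: np.ndarray, target: np.ndarray):
    """Mean squared error over every entry; returns (loss, dloss/dprediction)."""
    if prediction.shape != target.shape:
        raise ValueError("prediction and target shapes disagree")
    diff = prediction - target
    return float(np.mean(diff**2)), 2.0 * diff / diff.size


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

class Adam:
    """Adam with classic (L2-coupled) weight decay."""

    def __init__(self, params, lr=0.01, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class PlateauScheduler:
    """Multiply the learning rate by `factor` when a loss stops improving."""

    def __init__(self, optimizer: Adam, factor=0.1, patience=20,
                 rel_threshold=1e-4, min_lr=1e-7):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.rel_threshold = rel_threshold
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, loss: float):
        if loss < self.best - self.rel_threshold * abs(self.best):
            self.best = loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.bad_epochs = 0


class EarlyStopper:
    """Stop when a validation metric stops improving; keeps the best state."""

    def __init__(self, patience=50, mode="max"):
        self.patience = patience
        self.sign = 1.0 if mode == "max" else -1.0
        self.best = -np.inf
        self.bad_epochs = 0
        self.best_state = None

    def step(self, metric: float, state) -> bool:
        """Record `state` if `metric` improved; return True to stop."""
        if self.sign * metric > self.best:
            self.best = self.sign * metric
            self.best_state = state
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        return self.bad_epochs > self.patience
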