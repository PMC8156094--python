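"""Minimal NumPy building blocks for the 1-D convolutional classifier.

Implements exactly the layers the fall-risk CNN needs — same-padded 1-D
convolution, batch normalization, ReLU, non-overlapping max pooling, a
dense head — with full backpropagation and an Adam optimizer.  All state is
plain float64 ndarrays; training is deterministic given the seed and is
single-threaded apart from BLAS matmuls (which are themselves
deterministic).

Internal array layout is channels-first: (batch, channels, length).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Conv1d:
    """Same-padded 1-D convolution (stride 1, odd kernel), He-initialized."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator):
        if kernel % 2 == 0 or kernel < 1:
            raise ValueError("kernel size must be a positive odd integer")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        scale = np.sqrt(2.0 / (in_ch * kernel))
        self.W = rng.normal(0.0, scale, (out_ch, in_ch, kernel))
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, L = x.shape
        if L < self.kernel:
            raise ValueError("input shorter than the convolution kernel")
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        cols = sliding_window_view(xp, self.kernel, axis=2)  # (B,C,L,K)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(
            B, L, C * self.kernel)
        y = cols @ self.W.reshape(self.out_ch, -1).T + self.b
        if train:
            self._cols, self._shape = cols, (B, C, L)
        return y.transpose(0, 2, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, L = self._shape
        K, p = self.kernel, self.kernel // 2
        dyt = dy.transpose(0, 2, 1)  # (B, L, F)
        flat_dy = dyt.reshape(-1, self.out_ch)
        flat_cols = self._cols.reshape(-1, C * K)
        self.dW = (flat_dy.T @ flat_cols).reshape(self.W.shape)
        self.db = flat_dy.sum(axis=0)
        dcols = (dyt @ self.W.reshape(self.out_ch, -1)).reshape(B, L, C, K)
        dcols = dcols.transpose(0, 2, 1, 3)  # (B, C, L, K)
        dxp = np.zeros((B, C, L + 2 * p))
        for k in range(K):
            dxp[:, :, k:k + L] += dcols[:, :, :, k]
        self._cols = None
        return dxp[:, :, p:p + L]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    @property
    def n_parameters(self) -> int:
        return self.W.size + self.b.size


class BatchNorm1d:
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n_ch)
        self.beta = np.zeros(n_ch)
        self.dgamma = np.zeros(n_ch)
        self.dbeta = np.zeros(n_ch)
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean \
                + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var \
                + self.momentum * var
            self._std = np.sqrt(var + self.eps)
            self._xhat = (x - mean[None, :, None]) / self._std[None, :, None]
            return self.gamma[None, :, None] * self._xhat \
                + self.beta[None, :, None]
        xhat = (x - self.running_mean[None, :, None]) / \
            np.sqrt(self.running_var + self.eps)[None, :, None]
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, L = dy.shape
        N = B * L
        self.dgamma = (dy * self._xhat).sum(axis=(0, 2))
        self.dbeta = dy.sum(axis=(0, 2))
        dxhat = dy * self.gamma[None, :, None]
        s1 = dxhat.sum(axis=(0, 2))[None, :, None]
        s2 = (dxhat * self._xhat).sum(axis=(0, 2))[None, :, None]
        dx = (dxhat - s1 / N - self._xhat * s2 / N) / \
            self._std[None, :, None]
        self._xhat = None
        return dx

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    @property
    def n_parameters(self) -> int:
        return self.gamma.size + self.beta.size


class ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx

    def params(self):
        return []

    n_parameters = 0


class MaxPool1d:
    """Non-overlapping max pooling; a trailing remainder is truncated."""

    def __init__(self, size: int = 2):
        if size < 1:
            raise ValueError("pool size must be positive")
        self.size = size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, L = x.shape
        Lp = (L // self.size) * self.size
        xr = x[:, :, :Lp].reshape(B, C, Lp // self.size, self.size)
        if train:
            self._arg = xr.argmax(axis=3)
            self._in_len = L
        return xr.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, Lo = dy.shape
        dxr = np.zeros((B, C, Lo, self.size))
        np.put_along_axis(dxr, self._arg[..., None], dy[..., None], axis=3)
        dx = np.zeros((B, C, self._in_len))
        dx[:, :, :Lo * self.size] = dxr.reshape(B, C, Lo * self.size)
        self._arg = None
        return dx

    def params(self):
        return []

    n_parameters = 0


class Flatten:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)

    def params(self):
        return []

    n_parameters = 0


class Dense:
    """Fully connected layer, Glorot-initialized."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.W = rng.normal(0.0, scale, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        dx = dy @ self.W.T
        self._x = None
        return dx

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    @property
    def n_parameters(self) -> int:
        return self.W.size + self.b.size


class Adam:
    """Adam with bias correction; updates parameters in place."""

    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = layers
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for layer in layers
                  for p, _ in layer.params()]
        self.v = [np.zeros_like(p) for layer in layers
                  for p, _ in layer.params()]

    def step(self):
        self.t += 1
        i = 0
        for layer in self.layers:
            for p, g in layer.params():
                self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
                self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
                mhat = self.m[i] / (1 - self.b1 ** self.t)
                vhat = self.v[i] / (1 - self.b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
                i += 1


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
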