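"""Minimal CNN building blocks on numpy arrays (NCHW, float32).

Each layer exposes ``forward(x, train)`` / ``backward(grad)`` and a
``params()`` list of (array, grad) pairs consumed by the optimizer.
Convolutions are im2col + GEMM; all operations are deterministic, so a
fixed initialization seed and batch order make training bit-reproducible.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    B, C, H, W = x.shape
    OH = (H + 2 * pad - kh) // stride + 1
    OW = (W + 2 * pad - kw) // stride + 1
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(B, C, kh, kw, OH, OW),
        strides=(s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride),
        writeable=False,
    )
    cols = np.ascontiguousarray(view).reshape(B, C * kh * kw, OH * OW)
    return cols, OH, OW


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    B, C, H, W = x_shape
    OH = (H + 2 * pad - kh) // stride + 1
    OW = (W + 2 * pad - kw) // stride + 1
    xp = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(B, C, kh, kw, OH, OW)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + stride * OH : stride, j : j + stride * OW : stride] += cols[:, :, i, j]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


class Conv2d(Layer):
    def __init__(self, c_in, c_out, k, stride=1, pad=0, bias=False, rng=None):
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        self.W = (rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.dW = np.zeros_like(self.W)
        self.b = np.zeros(c_out, dtype=np.float32) if bias else None
        self.db = np.zeros(c_out, dtype=np.float32) if bias else None

    def params(self):
        p = [(self.W, self.dW)]
        if self.b is not None:
            p.append((self.b, self.db))
        return p

    def forward(self, x, train=True):
        self._xshape = x.shape
        cols, OH, OW = _im2col(x, self.k, self.k, self.stride, self.pad)
        B = x.shape[0]
        self._cols = cols
        out = np.einsum("fk,bkp->bfp", self.W, cols, optimize=True)
        if self.b is not None:
            out += self.b[None, :, None]
        return out.reshape(B, self.c_out, OH, OW)

    def backward(self, grad):
        B = grad.shape[0]
        g = grad.reshape(B, self.c_out, -1)
        self.dW[...] = np.einsum("bfp,bkp->fk", g, self._cols, optimize=True)
        if self.b is not None:
            self.db[...] = g.sum(axis=(0, 2))
        dcols = np.einsum("fk,bfp->bkp", self.W, g, optimize=True)
        self._cols = None
        return _col2im(dcols, self._xshape, self.k, self.k, self.stride, self.pad)


class BatchNorm2d(Layer):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros(c, dtype=np.float32)
        self.dbeta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._xhat, self._inv = xhat, inv
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, grad):
        xhat, inv = self._xhat, self._inv
        self.dgamma[...] = (grad * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = grad.sum(axis=(0, 2, 3))
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        g = grad * self.gamma[None, :, None, None]
        dx = (
            g
            - g.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (g * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv[None, :, None, None]
        self._xhat = None
        return dx


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2d(Layer):
    def __init__(self, k=3, stride=2, pad=1):
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x, train=True):
        self._xshape = x.shape
        B, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2), constant_values=-np.inf)
        cols, OH, OW = _im2col(
            xp.reshape(B * C, 1, *xp.shape[2:]), self.k, self.k, self.stride, 0
        )
        cols = cols.reshape(B * C, self.k * self.k, OH * OW)
        self._arg = cols.argmax(axis=1)
        out = np.take_along_axis(cols, self._arg[:, None, :], axis=1)[:, 0, :]
        self._ohw = (OH, OW)
        return out.reshape(B, C, OH, OW)

    def backward(self, grad):
        B, C, H, W = self._xshape
        OH, OW = self._ohw
        g = grad.reshape(B * C, OH * OW)
        cols = np.zeros((B * C, self.k * self.k, OH * OW), dtype=grad.dtype)
        np.put_along_axis(cols, self._arg[:, None, :], g[:, None, :], axis=1)
        Hp, Wp = H + 2 * self.pad, W + 2 * self.pad
        xp = _col2im(cols.reshape(B * C, self.k * self.k, OH * OW), (B * C, 1, Hp, Wp),
                     self.k, self.k, self.stride, 0)
        xp = xp.reshape(B, C, Hp, Wp)
        if self.pad:
            return xp[:, :, self.pad : -self.pad, self.pad : -self.pad]
        return xp


class GlobalAvgPool(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        B, C, H, W = self._shape
        return np.broadcast_to(grad[:, :, None, None] / (H * W), self._shape).astype(grad.dtype)


class Linear(Layer):
    def __init__(self, n_in, n_out, rng=None):
        rng = rng or np.random.default_rng(0)
        bound = np.sqrt(1.0 / n_in)
        self.W = rng.uniform(-bound, bound, size=(n_out, n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad):
        self.dW[...] = grad.T @ self._x
        self.db[...] = grad.sum(axis=0)
        dx = grad @ self.W
        self._x = None
        return dx


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad
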