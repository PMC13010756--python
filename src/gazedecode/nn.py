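"""Minimal seeded CNN machinery (conv / pool / dense, SGDM) on numpy.

Only what the condition decoder needs: im2col convolution, ReLU, max
pooling, dropout, dense layers, softmax cross-entropy, and stochastic
gradient descent with momentum and L2 weight decay. Everything is float32,
fully deterministic given the initialisation seed, and sized for small
inputs on a single CPU.

Tensors are NCHW; dense layers take (N, features).
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base layer: forward/backward plus (param, grad, velocity) triples."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[list[np.ndarray]]:
        return []


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    strides = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, oh, ow),
        strides=(strides[0], strides[1], strides[2], strides[3],
                 strides[2] * stride, strides[3] * stride),
        writeable=False,
    )
    # (n, oh, ow, c*kh*kw)
    return cols.transpose(0, 4, 5, 1, 2, 3).reshape(n, oh, ow, -1), oh, ow


class Conv2d(Layer):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel * kernel
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(c_out, c_in, kernel, kernel)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.vw = np.zeros_like(self.w)
        self.vb = np.zeros_like(self.b)

    def forward(self, x, train=False):
        self._xshape = x.shape
        cols, oh, ow = _im2col(x, self.kernel, self.kernel, self.stride,
                               self.pad)
        self._cols = cols if train else None
        wmat = self.w.reshape(self.w.shape[0], -1)
        out = cols @ wmat.T + self.b
        return out.transpose(0, 3, 1, 2).copy()

    def backward(self, grad):
        n, c_out, oh, ow = grad.shape
        g = grad.transpose(0, 2, 3, 1).reshape(-1, c_out)  # (n*oh*ow, c_out)
        cols = self._cols.reshape(-1, self._cols.shape[-1])
        self.gw[...] = (g.T @ cols).reshape(self.w.shape)
        self.gb[...] = g.sum(axis=0)
        wmat = self.w.reshape(c_out, -1)
        gcols = (g @ wmat).reshape(n, oh, ow, -1)  # (n, oh, ow, c*k*k)
        # col2im (scatter-add)
        _, c_in, h, w = self._xshape
        k, s, p = self.kernel, self.stride, self.pad
        gx = np.zeros((n, c_in, h + 2 * p, w + 2 * p), dtype=np.float32)
        gcols = gcols.reshape(n, oh, ow, c_in, k, k)
        for ky in range(k):
            for kx in range(k):
                gx[:, :, ky:ky + s * oh:s, kx:kx + s * ow:s] += (
                    gcols[:, :, :, :, ky, kx].transpose(0, 3, 1, 2)
                )
        if p:
            gx = gx[:, :, p:-p, p:-p]
        return gx

    def params(self):
        return [[self.w, self.gw, self.vw], [self.b, self.gb, self.vb]]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class MaxPool2d(Layer):
    def __init__(self, kernel: int = 2, stride: int | None = None):
        self.kernel = kernel
        self.stride = stride or kernel

    def forward(self, x, train=False):
        cols, oh, ow = _im2col(
            x.reshape(x.shape[0] * x.shape[1], 1, *x.shape[2:]),
            self.kernel, self.kernel, self.stride, 0,
        )
        cols = cols.reshape(x.shape[0], x.shape[1], oh, ow, -1)
        self._argmax = cols.argmax(axis=-1)
        self._xshape = x.shape
        return cols.max(axis=-1)

    def backward(self, grad):
        n, c, h, w = self._xshape
        oh, ow = grad.shape[2:]
        k, s = self.kernel, self.stride
        gx = np.zeros((n, c, h, w), dtype=np.float32)
        if s >= k:  # non-overlapping windows: pure slicing, no scatter
            for ky in range(k):
                for kx in range(k):
                    sel = self._argmax == ky * k + kx
                    gx[:, :, ky:ky + s * oh:s, kx:kx + s * ow:s] += (
                        np.where(sel, grad, 0.0))
            return gx
        ky = self._argmax // k
        kx = self._argmax % k
        oy = np.arange(oh)[None, None, :, None]
        ox = np.arange(ow)[None, None, None, :]
        iy = oy * s + ky
        ix = ox * s + kx
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        np.add.at(gx, (ni, ci, iy, ix), grad)
        return gx


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in),
                            size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.vw = np.zeros_like(self.w)
        self.vb = np.zeros_like(self.b)

    def forward(self, x, train=False):
        self._x = x if train else None
        return x @ self.w + self.b

    def backward(self, grad):
        self.gw[...] = self._x.T @ grad
        self.gb[...] = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [[self.w, self.gw, self.vw], [self.b, self.gb, self.vb]]


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def state(self) -> list[np.ndarray]:
        return [p[0].copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state):
            p[0][...] = s


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray,
                          targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits.

    ``targets`` are integer class indices.
    """
    n = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    loss = -np.mean(np.log(probs[np.arange(n), targets] + 1e-12))
    grad = probs
    grad[np.arange(n), targets] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


class SGDM:
    """Stochastic gradient descent with momentum and L2 weight decay."""

    def __init__(self, momentum: float = 0.9, l2: float = 1e-4):
        self.momentum = momentum
        self.l2 = l2

    def step(self, params, lr: float) -> None:
        for w, g, v in params:
            v *= self.momentum
            v -= lr * (g + self.l2 * w)
            w += v
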