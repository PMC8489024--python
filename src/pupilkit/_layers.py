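"""Minimal NumPy neural-network layers with explicit backpropagation.

Each layer is a small object holding its parameters, caching what its
backward pass needs, and exposing ``forward(x)`` / ``backward(dy)``.
Convolution is evaluated as nine GEMMs (one per kernel offset) over
shifted views of the zero-padded input, which keeps memory proportional
to the activations and routes the heavy lifting through BLAS.

Array layout is (N, C, H, W) throughout.  The default dtype is float32;
float64 is supported so finite-difference gradient checks can run at full
precision.
"""

from __future__ import annotations

import numpy as np

from ._kernels import conv3_backward_input, conv3_forward, conv3_grad_w


class Conv2d:
    """Same-padding 2D convolution with bias (odd square kernels).

    3×3 kernels run through the compiled direct-convolution kernels in
    :mod:`pupilkit._kernels`; other sizes (the 1×1 head) use the
    offset-sum GEMM path.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator, dtype=np.float32):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same-shape padding")
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.k = k
        self._x = None
        self.gW = None
        self.gb = None

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        p = k // 2
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else np.ascontiguousarray(x)
        self._x = xp
        c_out = self.W.shape[0]
        if k == 3:
            y = np.empty((n, c_out, h, w), dtype=x.dtype)
            conv3_forward(xp, self.W, self.b, y)
            return y
        y = np.zeros((n, c_out, h, w), dtype=x.dtype)
        for ki in range(k):
            for kj in range(k):
                xs = xp[:, :, ki:ki + h, kj:kj + w]
                # (c_out, c) x (n, c, h, w) -> (c_out, n, h, w)
                y += np.tensordot(self.W[:, :, ki, kj], xs, axes=([1], [1])).transpose(1, 0, 2, 3)
        y += self.b[None, :, None, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k = self.k
        p = k // 2
        xp = self._x
        n, c_out, h, w = dy.shape
        self.gb = dy.sum(axis=(0, 2, 3))
        if k == 3:
            dy = np.ascontiguousarray(dy)
            self.gW = np.empty_like(self.W)
            conv3_grad_w(xp, dy, self.gW)
            self._x = None
            return conv3_backward_input(dy, self.W)
        self.gW = np.zeros_like(self.W)
        dxp = np.zeros_like(xp)
        for ki in range(k):
            for kj in range(k):
                xs = xp[:, :, ki:ki + h, kj:kj + w]
                self.gW[:, :, ki, kj] = np.tensordot(dy, xs, axes=([0, 2, 3], [0, 2, 3]))
                dxp[:, :, ki:ki + h, kj:kj + w] += np.tensordot(
                    self.W[:, :, ki, kj], dy, axes=([0], [1])
                ).transpose(1, 0, 2, 3)
        self._x = None
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class ReLU:
    def __init__(self):
        self._mask = None

    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        m, self._mask = self._mask, None
        return dy * m


class MaxPool2:
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def __init__(self):
        self._idx = None
        self._shape = None

    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 requires even spatial dimensions")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        self._idx = None
        return dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class UpsampleNearest2:
    """Parameter-free nearest-neighbor x2 upsampling."""

    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class GlobalAvgPool:
    params: list = []
    grads: list = []

    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], (n, c, h, w)).astype(dy.dtype) / (h * w)


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self._x = None
        self.gW = None
        self.gb = None

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.gW = dy.T @ self._x
        self.gb = dy.sum(axis=0)
        x, self._x = self._x, None
        return dy @ self.W


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Element-wise binary cross-entropy from logits (stable form)."""
    return np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
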