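"""Minimal CPU neural-network primitives for the encoder–decoder segmenter.

Layers operate on float32 arrays in (N, C, H, W) layout.  Convolutions are
evaluated as BLAS matrix products over im2col patch matrices (built with
stride tricks, so the patch view costs no copy until the reshape); the
backward pass scatters patch gradients back with k*k vectorized adds.
Everything is deterministic given the seeds handed to the initializers.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with its gradient and Adam moment buffers."""

    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class Adam:
    """Adam optimizer over a flat list of :class:`Param`."""

    def __init__(self, params: Sequence[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for p in self.params:
            p.m = b1 * p.m + (1 - b1) * p.grad
            p.v = b2 * p.v + (1 - b2) * (p.grad * p.grad)
            p.value -= self.lr * (p.m / bias1) / (np.sqrt(p.v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad.fill(0.0)


class Conv2D:
    """Same-padding 2D convolution, He-initialized."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        fan_in = c_in * kernel * kernel
        std = math.sqrt(2.0 / fan_in)
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(rng.normal(0.0, std, size=(c_out, fan_in)).astype(np.float32))
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        # asymmetric padding keeps even kernels size-preserving
        self.pad = ((kernel - 1) // 2, kernel // 2)

    @property
    def params(self):
        return [self.w, self.b]

    @staticmethod
    def _im2col(x: np.ndarray, k: int, pad: tuple[int, int]) -> np.ndarray:
        """(N, C, H, W) -> contiguous (N*H*W, C*k*k) patch matrix."""
        pt, pb = pad
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pt, pb)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))       # (N,C,H,W,k,k)
        patches = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        return np.ascontiguousarray(patches, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        patches = self._im2col(x, self.kernel, self.pad)
        out = patches @ self.w.value.T + self.b.value
        self._cache = (patches, x.shape)
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        patches, x_shape = self._cache
        n, c, h, w = x_shape
        k = self.kernel
        pt, pb = self.pad
        dflat = np.ascontiguousarray(
            dout.transpose(0, 2, 3, 1).reshape(-1, self.c_out), dtype=np.float32)
        self.w.grad += dflat.T @ patches
        self.b.grad += dflat.sum(axis=0)
        # dx is the same-padding correlation of dout with the flipped kernel
        # (channels transposed, pads swapped), so it reuses the im2col GEMM
        # instead of k*k scatter-adds.
        w_flip = self.w.value.reshape(self.c_out, self.c_in, k, k)[:, :, ::-1, ::-1]
        w_back = np.ascontiguousarray(
            w_flip.transpose(1, 0, 2, 3).reshape(self.c_in, self.c_out * k * k))
        dpatches = self._im2col(np.ascontiguousarray(dout, dtype=np.float32),
                                k, (pb, pt))
        dx = dpatches @ w_back.T
        self._cache = None
        return dx.reshape(n, h, w, c).transpose(0, 3, 1, 2)


class BatchNorm2D:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels, dtype=np.float32))
        self.beta = Param(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    @property
    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        out = (self.gamma.value[None, :, None, None] * xhat
               + self.beta.value[None, :, None, None])
        if train:
            self._cache = (xhat, inv, x.shape)
        return out.astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        dxhat = dout * g
        sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (inv[None, :, None, None] / m) * (m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)
        self._cache = None
        return dx.astype(np.float32)


class ReLU:
    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        out = dout * self._mask
        self._mask = None
        return out


class MaxPool2x2:
    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        self._argmax = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dflat, self._argmax[..., None], dout[..., None], axis=-1)
        dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._argmax = None
        return dx.reshape(n, c, h, w)


class UpsampleNearest2x:
    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss_and_grad(prob: np.ndarray, target: np.ndarray,
                      eps: float = 1e-7) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the pre-sigmoid logit."""
    p = np.clip(prob, eps, 1.0 - eps)
    t = target.astype(np.float32)
    loss = float(-(t * np.log(p) + (1 - t) * np.log(1 - p)).mean())
    dlogit = (prob - t) / prob.size
    return loss, dlogit.astype(np.float32)
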