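"""Minimal volumetric neural-network primitives with manual backpropagation.

All layers operate on single volumes shaped ``(C, D, H, W)`` (batch of one,
matching the training regime where batch normalization degenerates to
instance normalization).  Each layer caches what its backward pass needs;
``backward`` must be called after ``forward`` with a gradient of the same
shape as the output.

Parameters are stored as ``Param`` objects holding the value and the
accumulated gradient, so an optimizer can walk ``model.parameters()``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


# Compute dtype; float64 is used by the gradient-check tests.
DTYPE = np.float32


class Param:
    """A trainable array with its gradient and optimizer slots."""

    __slots__ = ("value", "grad", "state")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.state: dict = {}

    @property
    def size(self) -> int:
        return self.value.size


class Conv3d:
    """Same-padding convolution, stride 1, odd kernel (3x3x3 or 1x1x1).

    Implemented as a sum of shifted channel-mixing matmuls rather than
    im2col: for small channel counts this avoids the large column-matrix
    copies and is several times faster on CPU.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in = c_in * kernel ** 3
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Param(rng.normal(0.0, std, (c_out, c_in, kernel, kernel, kernel)))
        self.bias = Param(np.zeros(c_out))
        self._x: np.ndarray | None = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        spatial = x.shape[1:]
        if self.k == 1:
            self._x = x
            w = self.weight.value.reshape(self.c_out, self.c_in)
            y = w @ x.reshape(self.c_in, -1) + self.bias.value[:, None]
            return y.reshape(self.c_out, *spatial)
        d, h, w0 = spatial
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))
        y = np.empty((self.c_out, d * h * w0), dtype=x.dtype)
        y[:] = self.bias.value[:, None]
        wv = self.weight.value
        shifted = []  # cached contiguous shifted views, reused by backward
        for di in range(self.k):
            for dj in range(self.k):
                for dk in range(self.k):
                    xs = np.ascontiguousarray(
                        xp[:, di:di + d, dj:dj + h, dk:dk + w0]
                    ).reshape(self.c_in, -1)
                    shifted.append(xs)
                    y += wv[:, :, di, dj, dk] @ xs
        self._shifted = shifted
        self._spatial = spatial
        return y.reshape(self.c_out, *spatial)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dyf = dy.reshape(self.c_out, -1)
        self.bias.grad += dyf.sum(axis=1)
        if self.k == 1:
            x = self._x
            self.weight.grad += (dyf @ x.reshape(self.c_in, -1).T).reshape(
                self.weight.value.shape
            )
            w = self.weight.value.reshape(self.c_out, self.c_in)
            dx = (w.T @ dyf).reshape(x.shape)
            self._x = None
            return dx
        d, h, w0 = self._spatial
        pad = self.k // 2
        dxp = np.zeros(
            (self.c_in, d + 2 * pad, h + 2 * pad, w0 + 2 * pad), dtype=dy.dtype
        )
        wv = self.weight.value
        wg = self.weight.grad
        o = 0
        for di in range(self.k):
            for dj in range(self.k):
                for dk in range(self.k):
                    xs = self._shifted[o]
                    o += 1
                    wg[:, :, di, dj, dk] += dyf @ xs.T
                    dxp[:, di:di + d, dj:dj + h, dk:dk + w0] += (
                        wv[:, :, di, dj, dk].T @ dyf
                    ).reshape(self.c_in, d, h, w0)
        self._shifted = None
        return dxp[:, pad:pad + d, pad:pad + h, pad:pad + w0]


class ReLU:
    def parameters(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class InstanceBatchNorm:
    """Batch norm at batch size one: per-channel statistics over the volume."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.eps = eps

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c = x.shape[0]
        flat = x.reshape(c, -1)
        self._mu = flat.mean(axis=1, keepdims=True)
        var = flat.var(axis=1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (flat - self._mu) * self._inv
        y = self.gamma.value[:, None] * self._xhat + self.beta.value[:, None]
        return y.reshape(x.shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c = dy.shape[0]
        dyf = dy.reshape(c, -1)
        n = dyf.shape[1]
        self.gamma.grad += (dyf * self._xhat).sum(axis=1)
        self.beta.grad += dyf.sum(axis=1)
        g = self.gamma.value[:, None]
        dxhat = dyf * g
        dx = (self._inv / n) * (
            n * dxhat
            - dxhat.sum(axis=1, keepdims=True)
            - self._xhat * (dxhat * self._xhat).sum(axis=1, keepdims=True)
        )
        return dx.reshape(dy.shape)


class MaxPool3d:
    """2x2x2 max pooling with stride 2; spatial dims must be even."""

    def parameters(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        blocks = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        blocks = blocks.transpose(0, 1, 3, 5, 2, 4, 6).reshape(c, d // 2, h // 2, w // 2, 8)
        self._arg = blocks.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(blocks, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, d, h, w = self._shape
        blocks = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=dy.dtype)
        np.put_along_axis(blocks, self._arg[..., None], dy[..., None], axis=-1)
        blocks = blocks.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
        return blocks.transpose(0, 1, 4, 2, 5, 3, 6).reshape(c, d, h, w)


class NearestUpsample3d:
    """Nearest-neighbor 2x upsampling in every spatial dimension."""

    def parameters(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, d, h, w = dy.shape
        return (
            dy.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
            .sum(axis=(2, 4, 6))
        )


def softmax(logits: np.ndarray) -> np.ndarray:
    """Channel-wise softmax for ``(K, ...)`` logits."""
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, target: np.ndarray, class_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Per-voxel weighted cross-entropy.

    Returns ``(loss, dlogits)`` where the loss is normalized by the total
    voxel weight so its scale is invariant to volume size and weighting.
    """
    k = logits.shape[0]
    p = softmax(logits.reshape(k, -1))
    t = target.reshape(-1)
    n = t.size
    w = class_weights[t].astype(np.float64)
    wsum = w.sum()
    logp = np.log(np.maximum(p[t, np.arange(n)], 1e-12))
    loss = float(-(w * logp).sum() / wsum)
    dlog = p * (w / wsum)
    dlog[t, np.arange(n)] -= w / wsum
    return loss, dlog.astype(DTYPE).reshape(logits.shape)


class AMSGrad:
    """AMSGrad variant of Adam (maintains the running max of v-hat)."""

    def __init__(self, params, lr: float = 3e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        for p in self.params:
            p.state["m"] = np.zeros_like(p.value)
            p.state["v"] = np.zeros_like(p.value)
            p.state["vmax"] = np.zeros_like(p.value)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for p in self.params:
            m, v, vmax = p.state["m"], p.state["v"], p.state["vmax"]
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            np.maximum(vmax, v / c2, out=vmax)
            p.value -= self.lr * (m / c1) / (np.sqrt(vmax) + self.eps)
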