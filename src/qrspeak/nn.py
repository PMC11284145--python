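"""Minimal 1-D neural-network layers with explicit gradients.

A small, self-contained layer library in numpy: each layer implements
``forward`` (caching what its gradient needs) and ``backward`` (returning
the gradient with respect to its input and accumulating parameter
gradients).  Layout is channels-first: activations are float32 arrays of
shape ``(batch, channels, length)``.

Gradient correctness is verified against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


def _pad_same(x: np.ndarray, k: int) -> np.ndarray:
    p = (k - 1) // 2
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p)))


class Conv1d(Layer):
    """Dense 1-D convolution, odd kernel, 'same' padding, optional stride.

    Output length is ``ceil(L / stride)``.  Weight shape ``(k, cin, cout)``.
    """

    def __init__(self, cin, cout, k, stride=1, bias=False, rng=None, name=""):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (k * cin))
        self.w = Param(rng.normal(0.0, scale, size=(k, cin, cout)), name + ".w")
        self.b = Param(np.zeros(cout), name + ".b") if bias else None
        self.k, self.stride = k, stride
        self.cin, self.cout = cin, cout

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        Lo = -(-L // self.stride)
        xp = _pad_same(x, self.k)
        # ensure taps can index (Lo-1)*stride + k - 1
        need = (Lo - 1) * self.stride + self.k
        if xp.shape[2] < need:
            xp = np.pad(xp, ((0, 0), (0, 0), (0, need - xp.shape[2])))
        self._xp, self._L = xp, L
        out = np.zeros((B, Lo, self.cout), dtype=DTYPE)
        w = self.w.value
        for t in range(self.k):
            xs = xp[:, :, t : t + (Lo - 1) * self.stride + 1 : self.stride]
            out += np.matmul(xs.transpose(0, 2, 1), w[t])
        out = out.transpose(0, 2, 1)
        if self.b is not None:
            out = out + self.b.value[None, :, None]
        return np.ascontiguousarray(out)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xp, L = self._xp, self._L
        B = gy.shape[0]
        Lo = gy.shape[2]
        gyT = np.ascontiguousarray(gy.transpose(0, 2, 1))  # (B, Lo, O)
        gxp = np.zeros_like(xp)
        w = self.w.value
        for t in range(self.k):
            sl = slice(t, t + (Lo - 1) * self.stride + 1, self.stride)
            xs = xp[:, :, sl]  # (B, C, Lo)
            self.w.grad[t] += np.tensordot(xs, gyT, axes=([0, 2], [0, 1]))
            gxp[:, :, sl] += np.matmul(gyT, w[t].T).transpose(0, 2, 1)
        if self.b is not None:
            self.b.grad += gy.sum(axis=(0, 2))
        p = (self.k - 1) // 2
        return gxp[:, :, p : p + L]


class DepthwiseConv1d(Layer):
    """Per-channel 1-D convolution, odd kernel, stride 1, 'same' padding."""

    def __init__(self, c, k, bias=False, rng=None, name=""):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / k)
        self.w = Param(rng.normal(0.0, scale, size=(c, k)), name + ".w")
        self.b = Param(np.zeros(c), name + ".b") if bias else None
        self.k, self.c = k, c

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        xp = _pad_same(x, self.k)
        self._xp, self._L = xp, L
        out = np.zeros((B, C, L), dtype=DTYPE)
        w = self.w.value
        for t in range(self.k):
            out += w[None, :, t, None] * xp[:, :, t : t + L]
        if self.b is not None:
            out += self.b.value[None, :, None]
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xp, L = self._xp, self._L
        gxp = np.zeros_like(xp)
        w = self.w.value
        for t in range(self.k):
            xs = xp[:, :, t : t + L]
            self.w.grad[:, t] += np.einsum("bcl,bcl->c", xs, gy)
            gxp[:, :, t : t + L] += w[None, :, t, None] * gy
        if self.b is not None:
            self.b.grad += gy.sum(axis=(0, 2))
        p = (self.k - 1) // 2
        return gxp[:, :, p : p + L]


class InstanceNorm(Layer):
    """Per-example, per-channel normalization over the length axis.

    No affine parameters: the statistics are recomputed per instance at
    train and test time alike, so inference is deterministic and the
    preceding convolution needs no bias.
    """

    def __init__(self, eps: float = 1e-5):
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=2, keepdims=True)
        var = x.var(axis=2, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self._xhat.astype(DTYPE, copy=False)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        gmean = gy.mean(axis=2, keepdims=True)
        gdot = (gy * xhat).mean(axis=2, keepdims=True)
        return (inv * (gy - gmean - xhat * gdot)).astype(DTYPE, copy=False)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(DTYPE, copy=False)

    def backward(self, gy):
        return np.where(self._mask, gy, 0.0).astype(DTYPE, copy=False)


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y.astype(DTYPE, copy=False)

    def backward(self, gy):
        y = self._y
        return (gy * y * (1.0 - y)).astype(DTYPE, copy=False)


def box_filter(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with zero padding (same length).

    Symmetric kernel, so the operator is self-adjoint: the backward pass
    is the same moving average applied to the gradient.
    """
    if width % 2 == 0:
        raise ValueError("box width must be odd")
    p = (width - 1) // 2
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(p, p)])
    cs = np.cumsum(xp, axis=-1, dtype=np.float64)
    cs = np.concatenate([np.zeros_like(cs[..., :1]), cs], axis=-1)
    out = (cs[..., width:] - cs[..., :-width]) / width
    return out.astype(DTYPE)


class BoxPool(Layer):
    """Stride-1 average pooling of odd width, same-length output."""

    def __init__(self, width: int):
        self.width = width

    def forward(self, x):
        return box_filter(x, self.width)

    def backward(self, gy):
        return box_filter(gy, self.width)


def upsample_nearest(x: np.ndarray, target_len: int) -> np.ndarray:
    """Nearest-neighbour 2x upsampling along the last axis, cropped."""
    out = np.repeat(x, 2, axis=-1)
    return out[..., :target_len]


def upsample_nearest_backward(gy: np.ndarray, source_len: int) -> np.ndarray:
    """Adjoint of :func:`upsample_nearest`."""
    Lt = gy.shape[-1]
    pad = 2 * source_len - Lt
    if pad:
        gy = np.pad(gy, [(0, 0)] * (gy.ndim - 1) + [(0, pad)])
    return gy.reshape(*gy.shape[:-1], source_len, 2).sum(axis=-1).astype(DTYPE)


class Adam:
    """Adam optimizer with L2-style weight decay folded into the gradient."""

    def __init__(self, params: list[Param], lr=1e-3, betas=(0.9, 0.999),
                 eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad.astype(np.float64)
            if self.wd:
                g = g + self.wd * p.value
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= (self.lr * (m / bc1) /
                        (np.sqrt(v / bc2) + self.eps)).astype(DTYPE)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
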