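"""Minimal explicit-backprop layer stack used by the generator/discriminator.

Tensors are ``float32`` NCHW arrays. Every layer caches what its backward
pass needs on ``forward`` and returns the input gradient from ``backward``;
parameter gradients accumulate into ``Param.grad`` (call ``zero_grad``
between optimization steps). Convolutions use im2col/col2im so the heavy
lifting is a single BLAS matmul per layer.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2D",
    "ConvTranspose2D",
    "BatchNorm2D",
    "Dropout",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "Sequential",
    "he_normal",
]

DTYPE = np.float32


class Param:
    """A learnable tensor with an accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """Truncated-normal He initialization (std sqrt(2/fan_in), cut at 2 std).

    Out-of-band draws are redrawn, matching the usual truncated-normal
    convention rather than clipping.
    """
    std = np.sqrt(2.0 / fan_in)
    w = rng.standard_normal(shape)
    bad = np.abs(w) > 2.0
    while bad.any():
        w[bad] = rng.standard_normal(int(bad.sum()))
        bad = np.abs(w) > 2.0
    return (w * std).astype(DTYPE)


def _im2col(x: np.ndarray, k: int, s: int, p: int):
    """(N,C,H,W) -> columns (N, C*k*k, OH*OW) plus output spatial dims."""
    n, c, h, w = x.shape
    if p:
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    oh = (h + 2 * p - k) // s + 1
    ow = (w + 2 * p - k) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::s, ::s]  # (N, C, OH, OW, k, k)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, oh * ow)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(cols: np.ndarray, x_shape, k: int, s: int, p: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add columns back to image space."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * p, w + 2 * p
    oh = (h + 2 * p - k) // s + 1
    ow = (w + 2 * p - k) // s + 1
    cols6 = cols.reshape(n, c, k, k, oh, ow)
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + s * oh : s, j : j + s * ow : s] += cols6[:, :, i, j]
    if p:
        out = out[:, :, p : p + h, p : p + w]
    return out


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """k x k convolution, stride ``s``, symmetric zero padding ``p``."""

    def __init__(self, in_c: int, out_c: int, k: int = 4, s: int = 2, p: int = 1,
                 rng: np.random.Generator | None = None, name: str = "conv"):
        self.in_c, self.out_c, self.k, self.s, self.p = in_c, out_c, k, s, p
        rng = rng or np.random.default_rng()
        self.w = Param(f"{name}.w", he_normal(rng, (out_c, in_c * k * k), in_c * k * k))
        self.b = Param(f"{name}.b", np.zeros(out_c, dtype=DTYPE))
        self._cache = None

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        return ((h + 2 * self.p - self.k) // self.s + 1,
                (w + 2 * self.p - self.k) // self.s + 1)

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False):
        cols, oh, ow = _im2col(x, self.k, self.s, self.p)
        y = self.w.value @ cols + self.b.value[None, :, None]
        self._cache = (cols, x.shape, oh, ow)
        n = x.shape[0]
        return y.reshape(n, self.out_c, oh, ow)

    def backward(self, gy):
        cols, x_shape, oh, ow = self._cache
        n = x_shape[0]
        gy_mat = gy.reshape(n, self.out_c, oh * ow)
        for i in range(n):
            self.w.grad += gy_mat[i] @ cols[i].T
        self.b.grad += gy_mat.sum(axis=(0, 2))
        gcols = np.stack([self.w.value.T @ gy_mat[i] for i in range(n)])
        return _col2im(gcols, x_shape, self.k, self.s, self.p)


class ConvTranspose2D(Layer):
    """Transposed (fractionally strided) convolution; adjoint of Conv2D.

    Output spatial size is ``s*(H-1) + k - 2p`` (= 2H for k=4, s=2, p=1).
    """

    def __init__(self, in_c: int, out_c: int, k: int = 4, s: int = 2, p: int = 1,
                 rng: np.random.Generator | None = None, name: str = "convT"):
        self.in_c, self.out_c, self.k, self.s, self.p = in_c, out_c, k, s, p
        rng = rng or np.random.default_rng()
        # weight maps in_c -> (out_c * k * k) columns; fan_in = in_c * k * k
        self.w = Param(f"{name}.w", he_normal(rng, (out_c * k * k, in_c), in_c * k * k))
        self.b = Param(f"{name}.b", np.zeros(out_c, dtype=DTYPE))
        self._cache = None

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        return (self.s * (h - 1) + self.k - 2 * self.p,
                self.s * (w - 1) + self.k - 2 * self.p)

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        oh, ow = self.out_shape(h, w)
        x_mat = x.reshape(n, c, h * w)
        cols = np.stack([self.w.value @ x_mat[i] for i in range(n)])
        y = _col2im(cols, (n, self.out_c, oh, ow), self.k, self.s, self.p)
        y += self.b.value[None, :, None, None]
        self._cache = (x_mat, (h, w), (n, self.out_c, oh, ow))
        return y

    def backward(self, gy):
        x_mat, (h, w), _y_shape = self._cache
        n = gy.shape[0]
        gcols, _, _ = _im2col(gy, self.k, self.s, self.p)  # (N, out_c*k*k, H*W)
        self.b.grad += gy.sum(axis=(0, 2, 3))
        gx = np.empty((n, self.in_c, h, w), dtype=gy.dtype)
        for i in range(n):
            self.w.grad += gcols[i] @ x_mat[i].T
            gx[i] = (self.w.value.T @ gcols[i]).reshape(self.in_c, h, w)
        return gx


class BatchNorm2D(Layer):
    """Per-channel normalization over the (N, H, W) axes.

    With batch size 1 the statistics are per-image, so this behaves like
    instance normalization — the regime the training recipe runs in.
    Inference uses running averages.
    """

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.9, name: str = "bn"):
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(f"{name}.gamma", np.ones(c, dtype=DTYPE))
        self.beta = Param(f"{name}.beta", np.zeros(c, dtype=DTYPE))
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        y = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        self._cache = (xhat, inv, training)
        return y.astype(DTYPE)

    def backward(self, gy):
        xhat, inv, training = self._cache
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not training:
            return gy * g * inv[None, :, None, None]
        m = gy.shape[0] * gy.shape[2] * gy.shape[3]
        gxhat = gy * g
        gx = (gxhat - gxhat.mean(axis=(0, 2, 3), keepdims=True)
              - xhat * (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
        return gx * inv[None, :, None, None]


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng()
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, gy):
        if self._mask is None:
            return gy
        return gy * self._mask


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, gy):
        return np.where(self._mask, gy, self.alpha * gy)


class Tanh(Layer):
    def forward(self, x, training=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, gy):
        return gy * (1.0 - self._y**2)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        out = []
        for l in self.layers:
            out.extend(l.params())
        return out

    def forward(self, x, training=False):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, gy):
        for l in reversed(self.layers):
            gy = l.backward(gy)
        return gy
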