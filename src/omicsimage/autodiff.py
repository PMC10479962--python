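"""Minimal convolutional neural-network layers with exact reverse-mode
gradients, in pure numpy.

Every layer caches what its backward pass needs during ``forward`` and
returns the gradient with respect to its input from ``backward``, while
accumulating parameter gradients in place.  The library is deliberately
small: strided convolution (im2col), transposed convolution (implemented as
the adjoint of convolution, so shapes invert exactly for any input size),
max pooling, batch normalization, leaky ReLU, and dense layers — the
ingredients of the encoder/decoder/extractor architecture.  Gradients flow
all the way back to the input image, which is what Integrated Gradients
differentiates.

All computation is float32; parameter gradients are accumulated until
:meth:`Layer.zero_grad`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


@dataclass
class Param:
    data: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.data = np.ascontiguousarray(self.data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)


# ---------------------------------------------------------------------------
# im2col / col2im
# ---------------------------------------------------------------------------


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    """Unfold (B, C, H, W) into (B, C*k*k, OH*OW) patch columns."""
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    cols = np.empty((b, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols.reshape(b, c * k * k, oh * ow), oh, ow


def col2im(
    cols: np.ndarray,
    x_shape: tuple[int, int, int, int],
    k: int,
    stride: int,
    pad: int,
    oh: int,
    ow: int,
) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patch columns back to an image."""
    b, c, h, w = x_shape
    xp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols6 = cols.reshape(b, c, k, k, oh, ow)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols6[
                :, :, i, j
            ]
    if pad:
        return xp[:, :, pad : pad + h, pad : pad + w]
    return xp


def conv_out_size(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class Layer:
    def params(self) -> list[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int = 3,
        stride: int = 1,
        pad: int = 1,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng()
        fan_in = c_in * k * k
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(c_out, fan_in))
        self.w = Param(w)
        self.b = Param(np.zeros(c_out))
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cols, oh, ow = im2col(x, self.k, self.stride, self.pad)
        out = np.matmul(self.w.data, cols)  # (B, c_out, oh*ow)
        out += self.b.data[None, :, None]
        self._cache = (x.shape, cols, oh, ow)
        return out.reshape(x.shape[0], self.c_out, oh, ow)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, cols, oh, ow = self._cache
        b = dout.shape[0]
        d2 = np.ascontiguousarray(dout.reshape(b, self.c_out, oh * ow))
        self.b.grad += d2.sum(axis=(0, 2))
        self.w.grad += np.matmul(d2, cols.transpose(0, 2, 1)).sum(axis=0)
        dcols = np.matmul(self.w.data.T, d2)
        return col2im(dcols, x_shape, self.k, self.stride, self.pad, oh, ow)


class ConvTranspose2d(Layer):
    """Transposed (fractionally strided) convolution.

    Implemented as the exact adjoint of :class:`Conv2d`, so the caller
    specifies the target output spatial size and any encoder size is
    inverted exactly (no output-padding bookkeeping).
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int = 3,
        stride: int = 2,
        pad: int = 1,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng()
        fan_in = c_in * k * k
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(c_in, c_out * k * k))
        self.w = Param(w)
        self.b = Param(np.zeros(c_out))
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        self.out_hw: tuple[int, int] | None = None
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if self.out_hw is None:
            raise RuntimeError("set out_hw before calling ConvTranspose2d.forward")
        b, c_in, h, w = x.shape
        oh, ow = self.out_hw
        if (
            conv_out_size(oh, self.k, self.stride, self.pad) != h
            or conv_out_size(ow, self.k, self.stride, self.pad) != w
        ):
            raise ValueError(
                f"out_hw {self.out_hw} is not consistent with input {h}x{w} "
                f"(k={self.k}, stride={self.stride}, pad={self.pad})"
            )
        x2 = x.reshape(b, c_in, h * w)
        dcols = np.matmul(self.w.data.T, x2)  # (B, c_out*k*k, h*w)
        out = col2im(dcols, (b, self.c_out, oh, ow), self.k, self.stride, self.pad, h, w)
        out += self.b.data[None, :, None, None]
        self._cache = (x2, (b, c_in, h, w))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x2, (b, c_in, h, w) = self._cache
        cols, oh2, ow2 = im2col(dout, self.k, self.stride, self.pad)
        assert (oh2, ow2) == (h, w)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        self.w.grad += np.matmul(x2, cols.transpose(0, 2, 1)).sum(axis=0)
        dx = np.matmul(self.w.data, cols)
        return dx.reshape(b, c_in, h, w)


class MaxPool2d(Layer):
    """Max pooling with window 2 along any axis longer than 1 (floor mode).

    Degenerate axes (height 1 in flat layouts) are left untouched so the
    same network code path works on 1-D gene vectors.  Gradient routes to
    the first maximum within each window.
    """

    def __init__(self) -> None:
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, h, w = x.shape
        kh = 2 if h > 1 else 1
        kw = 2 if w > 1 else 1
        h2, w2 = (h // kh) * kh, (w // kw) * kw
        win = x[:, :, :h2, :w2].reshape(b, c, h2 // kh, kh, w2 // kw, kw)
        flat = win.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h2 // kh, w2 // kw, kh * kw)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, kh, kw, h2, w2, idx)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, kh, kw, h2, w2, idx = self._cache
        b, c, h, w = x_shape
        oh, ow = h2 // kh, w2 // kw
        dflat = np.zeros((b, c, oh, ow, kh * kw), dtype=dout.dtype)
        np.put_along_axis(dflat, idx[..., None], dout[..., None], axis=-1)
        dwin = dflat.reshape(b, c, oh, ow, kh, kw).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros(x_shape, dtype=dout.dtype)
        dx[:, :, :h2, :w2] = dwin.reshape(b, c, h2, w2)
        return dx


class BatchNorm2d(Layer):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, train, x_shape = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None] * inv[None, :, None, None]
        if not train:
            return dout * g
        n = x_shape[0] * x_shape[2] * x_shape[3]
        dxhat = dout * self.gamma.data[None, :, None, None]
        mean_dxhat = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return inv[None, :, None, None] * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.01) -> None:
        self.alpha = alpha
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, self.alpha * dout)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng()
        self.w = Param(rng.normal(0.0, math.sqrt(2.0 / n_in), size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w.data + self.b.data

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.data.T


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


# ---------------------------------------------------------------------------
# Losses (return value and gradient w.r.t. the first argument)
# ---------------------------------------------------------------------------


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross entropy over the batch with its gradient w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), (dlogits / n).astype(logits.dtype)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error with gradient w.r.t. predictions."""
    pred = pred.reshape(-1)
    diff = pred.astype(np.float64) - target.astype(np.float64)
    loss = float((diff**2).mean())
    return loss, (2.0 * diff / diff.size).astype(DTYPE).reshape(-1, 1)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------


class Adagrad:
    """Adagrad with multiplicative learning-rate decay and L2 weight decay.

    Step ``t`` uses learning rate ``lr / (1 + (t - 1) * lr_decay)``; the
    per-parameter accumulator is the running sum of squared gradients.
    """

    def __init__(
        self,
        params: Sequence[Param],
        lr: float = 9.9e-5,
        lr_decay: float = 1e-6,
        weight_decay: float = 1e-6,
        eps: float = 1e-10,
    ) -> None:
        self.params = list(params)
        self.lr, self.lr_decay, self.weight_decay, self.eps = lr, lr_decay, weight_decay, eps
        self.state = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        clr = self.lr / (1.0 + (self.t - 1) * self.lr_decay)
        for p, acc in zip(self.params, self.state):
            g = p.grad.astype(np.float64)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            acc += g * g
            p.data -= (clr * g / (np.sqrt(acc) + self.eps)).astype(DTYPE)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0
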