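"""Trainable layers with explicit forward/backward passes.

Each layer caches what its backward pass needs on ``forward`` and releases
it on ``backward``. Parameters are ``Param`` objects holding the value and
the accumulated gradient, so an optimizer can walk ``layer.parameters()``.

Weight initialization is He-uniform (fan-in), drawn from a
``numpy.random.Generator`` supplied by the model builder so that identical
seeds give bitwise-identical networks.
"""
from __future__ import annotations

from typing import Iterable

import numpy as np

from .core import (
    col2im,
    conv2d_backward_data,
    conv2d_backward_weight,
    conv2d_forward,
    im2col,
)

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


def _he_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Layer:
    """Base: stateless layers override forward/backward only."""

    def parameters(self) -> Iterable[Param]:
        return ()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """Standard convolution, same-padding by default (pad = k//2)."""

    def __init__(self, c_in, c_out, k, rng, stride=1, pad=None, bias=False):
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        self.k = k
        self.weight = Param(_he_uniform(rng, (c_out, c_in, k, k), c_in * k * k))
        self.bias = Param(np.zeros(c_out, dtype=DTYPE)) if bias else None

    def parameters(self):
        return (self.weight, self.bias) if self.bias is not None else (self.weight,)

    def forward(self, x, train=True):
        self._x_shape = x.shape
        y, cols = conv2d_forward(x, self.weight.value, self.stride, self.pad)
        self._cols = cols if train else None
        if self.bias is not None:
            y += self.bias.value[None, :, None, None]
        return y

    def backward(self, dy):
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        self.weight.grad += conv2d_backward_weight(dy, self._cols, self.weight.value.shape)
        self._cols = None
        return conv2d_backward_data(dy, self.weight.value, self._x_shape, self.stride, self.pad)


class DepthwiseConv2d(Layer):
    """Per-channel 3×3 convolution, stride 1, same padding, no bias."""

    def __init__(self, c, k, rng):
        self.c, self.k = c, k
        self.weight = Param(_he_uniform(rng, (c, k * k), k * k))

    def parameters(self):
        return (self.weight,)

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        self._x_shape = x.shape
        cols = im2col(x, self.k, 1, self.k // 2).reshape(n, c, self.k * self.k, h * w)
        self._cols = cols if train else None
        y = np.einsum("ck,nckl->ncl", self.weight.value, cols, optimize=True)
        return y.reshape(n, c, h, w)

    def backward(self, dy):
        n, c, h, w = dy.shape
        dy_flat = dy.reshape(n, c, h * w)
        self.weight.grad += np.einsum("ncl,nckl->ck", dy_flat, self._cols, optimize=True)
        self._cols = None
        dcols = np.einsum("ck,ncl->nckl", self.weight.value, dy_flat, optimize=True)
        return col2im(dcols.reshape(n, c * self.k * self.k, h * w), self._x_shape, self.k, 1, self.k // 2)


class ConvTranspose2d(Layer):
    """3×3 transposed convolution, stride 2, exactly doubling H and W.

    Implemented as the data-gradient of the matching stride-2 convolution
    (kernel 3, pad 1, output-padding 1 in the usual framework phrasing).
    """

    def __init__(self, c_in, c_out, k, rng, bias=False):
        self.k = k
        self.pad = (k - 1) // 2
        self.c_in, self.c_out = c_in, c_out
        # weight laid out as the matching forward conv's (c_in, c_out, k, k)
        self.weight = Param(_he_uniform(rng, (c_in, c_out, k, k), c_in * k * k))
        self.bias = Param(np.zeros(c_out, dtype=DTYPE)) if bias else None

    def parameters(self):
        return (self.weight, self.bias) if self.bias is not None else (self.weight,)

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        self._x = x if train else None
        self._x_shape = x.shape
        y_shape = (n, self.c_out, 2 * h, 2 * w)
        self._y_shape = y_shape
        y = conv2d_backward_data(x, self.weight.value, y_shape, stride=2, pad=self.pad)
        if self.bias is not None:
            y += self.bias.value[None, :, None, None]
        return y

    def backward(self, dy):
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        cols = im2col(dy, self.k, 2, self.pad)
        self.weight.grad += conv2d_backward_weight(
            self._x, cols, self.weight.value.shape
        )
        dx, _ = conv2d_forward(dy, self.weight.value, 2, self.pad, cols=cols)
        self._x = None
        return dx


class BatchNorm2d(Layer):
    """Per-channel batch normalization.

    ``freeze_stats=True`` makes forward use the running statistics even in
    training mode (the layer then behaves as a fixed affine map); gradients
    are still cached, which is what Grad-CAM needs to differentiate an
    inference-mode network.
    """

    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = Param(np.ones(c, dtype=DTYPE))
        self.beta = Param(np.zeros(c, dtype=DTYPE))
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self.freeze_stats = False

    def parameters(self):
        return (self.gamma, self.beta)

    def forward(self, x, train=True):
        batch_stats = train and not self.freeze_stats
        if batch_stats:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        if train:
            self._xhat, self._inv_std = xhat, inv_std
            self._batch_stats = batch_stats
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy):
        xhat, inv_std = self._xhat, self._inv_std
        self._xhat = None
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None] * inv_std[None, :, None, None]
        if not self._batch_stats:
            return g * dy
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dy_sum = dy.sum(axis=(0, 2, 3))[None, :, None, None]
        dyx_sum = (dy * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return g * (dy - dy_sum / m - xhat * dyx_sum / m)


class ReLU(Layer):
    def forward(self, x, train=True):
        mask = x > 0
        self._mask = mask if train else None
        return x * mask

    def backward(self, dy):
        dy = dy * self._mask
        self._mask = None
        return dy


class MaxPool2d(Layer):
    """2×2 max pooling, stride 2; ties route the gradient to the first max."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(n, c, h // 2, w // 2, 4)
        idx = r.argmax(axis=-1)
        if train:
            self._idx, self._x_shape = idx, x.shape
        return np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, h, w = self._x_shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(out, self._idx[..., None], dy[..., None], axis=-1)
        self._idx = None
        out = out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return out.reshape(n, c, h, w)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self):
        for l in self.layers:
            yield from l.parameters()

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean per-pixel cross-entropy.

    logits (N,K,H,W), labels (N,H,W) int. Returns (loss, dlogits) with
    dlogits already divided by the number of pixels.
    """
    n, k, h, w = logits.shape
    p = softmax(logits, axis=1)
    flat = p.transpose(0, 2, 3, 1).reshape(-1, k)
    lab = labels.reshape(-1)
    picked = np.clip(flat[np.arange(lab.size), lab], 1e-12, None)
    loss = float(-np.log(picked).mean())
    dflat = flat.copy()
    dflat[np.arange(lab.size), lab] -= 1.0
    dflat /= lab.size
    dlogits = dflat.reshape(n, h, w, k).transpose(0, 3, 1, 2).astype(logits.dtype)
    return loss, dlogits
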