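"""Low-level convolution arithmetic on NCHW float32 arrays.

im2col/col2im based: a k×k convolution becomes one matrix product, its
data/weight gradients become the transposed products, and a stride-2
transposed convolution is exactly the data-gradient of the matching
stride-2 convolution (which is how it is implemented here).
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "conv_out_size",
    "im2col",
    "col2im",
    "conv2d_forward",
    "conv2d_backward_data",
    "conv2d_backward_weight",
]


def conv_out_size(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*k*k, L) patch matrix, L = Ho*Wo."""
    n, c, h, w = x.shape
    ho = conv_out_size(h, k, stride, pad)
    wo = conv_out_size(w, k, stride, pad)
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (n, c, k, k, ho, wo), (s0, s1, s2, s3, s2 * stride, s3 * stride)
    )
    return np.ascontiguousarray(view).reshape(n, c * k * k, ho * wo)


def col2im(cols: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of im2col: scatter-add patches back to (N,C,H,W)."""
    n, c, h, w = x_shape
    ho = conv_out_size(h, k, stride, pad)
    wo = conv_out_size(w, k, stride, pad)
    cols = cols.reshape(n, c, k, k, ho, wo)
    out = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[
                :, :, i, j
            ]
    if pad:
        out = out[:, :, pad : pad + h, pad : pad + w]
    return out


def conv2d_forward(x, weight, stride, pad, cols=None):
    """x (N,Cin,H,W), weight (Cout,Cin,k,k) -> (N,Cout,Ho,Wo). Returns (y, cols)."""
    n, _, h, w = x.shape
    cout, cin, k, _ = weight.shape
    if cols is None:
        cols = im2col(x, k, stride, pad)
    wm = weight.reshape(cout, cin * k * k)
    y = np.einsum("of,nfl->nol", wm, cols, optimize=True)
    ho = conv_out_size(h, k, stride, pad)
    wo = conv_out_size(w, k, stride, pad)
    return y.reshape(n, cout, ho, wo), cols


def conv2d_backward_data(dy, weight, x_shape, stride, pad):
    n = dy.shape[0]
    cout, cin, k, _ = weight.shape
    wm = weight.reshape(cout, cin * k * k)
    dy_flat = dy.reshape(n, cout, -1)
    dcols = np.einsum("of,nol->nfl", wm, dy_flat, optimize=True)
    return col2im(dcols, x_shape, k, stride, pad)


def conv2d_backward_weight(dy, cols, weight_shape):
    cout, cin, k, _ = weight_shape
    n = dy.shape[0]
    dy_flat = dy.reshape(n, cout, -1)
    dw = np.einsum("nol,nfl->of", dy_flat, cols, optimize=True)
    return dw.reshape(weight_shape)
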