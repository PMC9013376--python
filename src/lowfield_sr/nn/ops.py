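"""Convolutional primitives in numpy (channels-last NHWC, float32).

A SAME-padded convolution is computed as one fat GEMM followed by
shift-adds of the per-offset results:

    t[.., (i,j,:)] = x_padded @ W[i, j]          (single BLAS call)
    y[h, w]       += t[h*s + i, w*s + j, (i,j,:)] for each kernel offset

so the (potentially very wide, because of dense/skip concatenations) input
is streamed through BLAS exactly once and the per-offset work touches only
the narrow output channels. The backward pass mirrors this: the upstream
gradient is scattered into the offset layout, then one GEMM each yields the
weight and input gradients. No im2col matrix is ever materialized, keeping
both time and memory proportional to the feature maps themselves — this is
what makes a ~2M-parameter network tractable in pure numpy on one CPU.

Weight layouts:
* convolution: ``(k, k, c_in, c_out)``
* transpose convolution: ``(k, k, c_out, c_in)`` — the weight of the
  underlying strided convolution whose adjoint the layer computes.

The transpose convolution is exactly the adjoint of a stride-``s``
SAME-padded convolution; for kernel ``k >= s`` its output spatial size is
``s *`` input size.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "conv2d",
    "conv2d_backward",
    "conv_transpose2d",
    "conv_transpose2d_backward",
    "same_padding",
]


def same_padding(k: int, stride: int = 1) -> tuple[int, int]:
    """(begin, end) zero padding giving output size ceil(in/stride)."""
    total = max(k - stride, 0)
    beg = total // 2
    return beg, total - beg


def _pad(x: np.ndarray, pad: tuple[int, int]) -> np.ndarray:
    pb, pe = pad
    if pb == 0 and pe == 0:
        return np.ascontiguousarray(x)
    return np.pad(x, ((0, 0), (pb, pe), (pb, pe), (0, 0)))


def _window(a: np.ndarray, i: int, j: int, ho: int, wo: int, s: int):
    """The (i, j)-shifted stride-``s`` window of a padded NHWC array."""
    return a[:, i : i + s * (ho - 1) + 1 : s, j : j + s * (wo - 1) + 1 : s]


def conv2d(
    x: np.ndarray, w: np.ndarray, b: np.ndarray | None, stride: int = 1
) -> tuple[np.ndarray, tuple]:
    """SAME-padded 2D convolution (cross-correlation) in NHWC.

    Returns (output, cache); cache carries what the backward pass needs.
    """
    k, _, ci, co = w.shape
    pad = same_padding(k, stride)
    xp = _pad(x, pad)
    B, Hp, Wp, _ = xp.shape
    ho = (Hp - k) // stride + 1
    wo = (Wp - k) // stride + 1
    xp2 = xp.reshape(B * Hp * Wp, ci)
    w9 = np.ascontiguousarray(w.transpose(2, 0, 1, 3)).reshape(ci, k * k * co)
    t9 = (xp2 @ w9).reshape(B, Hp, Wp, k, k, co)
    y = np.zeros((B, ho, wo, co), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            y += _window(t9, i, j, ho, wo, stride)[:, :, :, i, j]
    if b is not None:
        y += b
    # cache the (shared) unpadded input, not the padded copy: backward re-pads
    cache = (x, (B, Hp, Wp), x.shape, stride, pad, (ho, wo))
    return y, cache


def conv2d_backward(
    dy: np.ndarray, w: np.ndarray, cache: tuple, with_bias: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Gradients of conv2d w.r.t. input, weights and bias."""
    x, (B, Hp, Wp), x_shape, stride, pad, (ho, wo) = cache
    k, _, ci, co = w.shape
    xp2 = _pad(x, pad).reshape(B * Hp * Wp, ci)
    dt9 = np.zeros((B, Hp, Wp, k, k, co), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            _window(dt9, i, j, ho, wo, stride)[:, :, :, i, j] = dy
    dt92 = dt9.reshape(B * Hp * Wp, k * k * co)
    dw9 = xp2.T @ dt92  # (ci, k*k*co)
    dw = np.ascontiguousarray(dw9.reshape(ci, k, k, co).transpose(1, 2, 0, 3))
    w9 = np.ascontiguousarray(w.transpose(2, 0, 1, 3)).reshape(ci, k * k * co)
    dxp = (dt92 @ w9.T).reshape(B, Hp, Wp, ci)
    pb = pad[0]
    H, W = x_shape[1], x_shape[2]
    dx = dxp[:, pb : pb + H, pb : pb + W] if (pad[0] or pad[1]) else dxp
    db = dy.sum(axis=(0, 1, 2)) if with_bias else None
    return dx, dw, db


def conv_transpose2d(
    x: np.ndarray, w: np.ndarray, b: np.ndarray | None, stride: int = 2
) -> tuple[np.ndarray, tuple]:
    """Transpose convolution in NHWC; w: (k, k, c_out, c_in), k >= stride.

    Computes the adjoint of the stride-``s`` SAME conv with weight ``w``;
    output spatial size is exactly ``stride *`` input size.
    """
    k, _, co, ci = w.shape
    if k < stride:
        raise ValueError(f"deconv kernel {k} must be >= stride {stride}")
    B, H, W, _ = x.shape
    s = stride
    pad = same_padding(k, s)
    pb, pe = pad
    Hs, Ws = H * s, W * s
    x2 = np.ascontiguousarray(x).reshape(B * H * W, ci)
    w9 = np.ascontiguousarray(w.transpose(3, 0, 1, 2)).reshape(ci, k * k * co)
    t9 = (x2 @ w9).reshape(B, H, W, k, k, co)
    del x2  # not needed past the GEMM; backward re-flattens the shared input
    yp = np.zeros((B, Hs + pb + pe, Ws + pb + pe, co), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            _window(yp, i, j, H, W, s)[...] += t9[:, :, :, i, j]
    y = yp[:, pb : pb + Hs, pb : pb + Ws] if (pb or pe) else yp
    if b is not None:
        y = y + b
    y = np.ascontiguousarray(y)
    cache = (x, (B, H, W, ci), stride, pad)
    return y, cache


def conv_transpose2d_backward(
    dy: np.ndarray, w: np.ndarray, cache: tuple, with_bias: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Gradients of conv_transpose2d: dx is the forward strided conv of dy."""
    x, x_shape, stride, pad = cache
    k, _, co, ci = w.shape
    B, H, W, _ = x_shape
    x2 = np.ascontiguousarray(x).reshape(B * H * W, ci)
    dyp = _pad(dy, pad)
    dt9 = np.empty((B, H, W, k, k, co), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            dt9[:, :, :, i, j] = _window(dyp, i, j, H, W, stride)
    dt92 = dt9.reshape(B * H * W, k * k * co)
    w9 = np.ascontiguousarray(w.transpose(3, 0, 1, 2)).reshape(ci, k * k * co)
    dx = (dt92 @ w9.T).reshape(x_shape)
    dw9 = x2.T @ dt92  # (ci, k*k*co)
    dw = np.ascontiguousarray(dw9.reshape(ci, k, k, co).transpose(1, 2, 3, 0))
    db = dy.sum(axis=(0, 1, 2)) if with_bias else None
    return dx, dw, db
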