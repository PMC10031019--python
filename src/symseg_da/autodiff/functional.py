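"""Convolutional primitives for the autodiff engine.

Convolutions use an im2col view + one BLAS matmul; the data gradient and
transposed convolution share a col2im scatter implemented with k*k strided
slice-adds (no np.add.at), which keeps everything vectorized and fast
enough for desk-scale CPU training.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .tensor import Tensor, is_grad_enabled

__all__ = [
    "conv2d",
    "conv_transpose2d",
    "depthwise_conv2d",
    "upsample_nearest2d",
    "linear",
    "global_avg_pool2d",
    "channel_pool",
]


def _pad_hw(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int) -> Tuple[np.ndarray, int, int]:
    """Return a contiguous (N, C*kh*kw, OH*OW) column matrix of padded input."""
    n, c, h, w = xp.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    sn, sc, sh, sw = xp.strides
    view = as_strided(
        xp,
        shape=(n, c, kh, kw, oh, ow),
        strides=(sn, sc, sh, sw, sh * stride, sw * stride),
    )
    cols = np.ascontiguousarray(view).reshape(n, c * kh * kw, oh * ow)
    return cols, oh, ow


def _col2im(
    cols6: np.ndarray, x_shape: Tuple[int, int, int, int], kh: int, kw: int, stride: int, pad: int
) -> np.ndarray:
    """Scatter-add a (N, C, kh, kw, OH, OW) column tensor back to an image."""
    n, c, h, w = x_shape
    oh, ow = cols6.shape[4], cols6.shape[5]
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols6[:, :, i, j]
    if pad == 0:
        return xp
    return xp[:, :, pad : pad + h, pad : pad + w]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D cross-correlation. weight: (F, C, kh, kw); bias: (F,) or None."""
    f, c, kh, kw = weight.data.shape
    n, cin, h, w = x.data.shape
    if cin != c:
        raise ValueError(f"conv2d channel mismatch: input has {cin}, weight expects {c}")
    xp = _pad_hw(x.data, pad)
    cols, oh, ow = _im2col(xp, kh, kw, stride)
    w2 = weight.data.reshape(f, c * kh * kw)
    out = np.matmul(w2, cols)  # (N, F, OH*OW)
    if bias is not None:
        out += bias.data.reshape(1, f, 1)
    out = out.reshape(n, f, oh, ow)

    req = (x.requires_grad or weight.requires_grad or (bias is not None and bias.requires_grad))
    if not (req and is_grad_enabled()):
        return Tensor(out)

    def _bw(g: np.ndarray) -> None:
        gl = g.reshape(n, f, oh * ow)
        if weight.requires_grad:
            dw = np.einsum("nfl,nkl->fk", gl, cols, optimize=True)
            weight._accumulate(dw.reshape(f, c, kh, kw))
        if bias is not None and bias.requires_grad:
            bias._accumulate(gl.sum(axis=(0, 2)))
        if x.requires_grad:
            dcols = np.matmul(w2.T, gl)  # (N, C*kh*kw, OH*OW)
            dcols6 = dcols.reshape(n, c, kh, kw, oh, ow)
            x._accumulate(_col2im(dcols6, (n, c, h, w), kh, kw, stride, pad))

    prev = (x, weight) if bias is None else (x, weight, bias)
    return Tensor(out, True, prev, _bw)


def conv_transpose2d(
    x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 2, pad: int = 1
) -> Tensor:
    """Transposed convolution. weight: (C_in, F, kh, kw).

    Output spatial size: (H-1)*stride - 2*pad + k.
    """
    c, f, kh, kw = weight.data.shape
    n, cin, h, w = x.data.shape
    if cin != c:
        raise ValueError(f"conv_transpose2d channel mismatch: input has {cin}, weight expects {c}")
    oh = (h - 1) * stride - 2 * pad + kh
    ow = (w - 1) * stride - 2 * pad + kw
    w2 = weight.data.reshape(c, f * kh * kw)
    xl = x.data.reshape(n, c, h * w)
    cols = np.einsum("ck,ncl->nkl", w2, xl, optimize=True)  # (N, F*kh*kw, H*W)
    cols6 = cols.reshape(n, f, kh, kw, h, w)
    out = _col2im(cols6, (n, f, oh, ow), kh, kw, stride, pad)
    if bias is not None:
        out = out + bias.data.reshape(1, f, 1, 1)

    req = (x.requires_grad or weight.requires_grad or (bias is not None and bias.requires_grad))
    if not (req and is_grad_enabled()):
        return Tensor(out)

    def _bw(g: np.ndarray) -> None:
        gp = _pad_hw(g, pad)
        gcols, goh, gow = _im2col(gp, kh, kw, stride)  # (N, F*kh*kw, H*W)
        assert goh == h and gow == w
        if weight.requires_grad:
            dw = np.einsum("ncl,nkl->ck", xl, gcols, optimize=True)
            weight._accumulate(dw.reshape(c, f, kh, kw))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dx = np.einsum("ck,nkl->ncl", w2, gcols, optimize=True)
            x._accumulate(dx.reshape(n, c, h, w))

    prev = (x, weight) if bias is None else (x, weight, bias)
    return Tensor(out, True, prev, _bw)


def depthwise_conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, pad: int = 1) -> Tensor:
    """Per-channel convolution. weight: (C, kh, kw)."""
    c, kh, kw = weight.data.shape
    n, cin, h, w = x.data.shape
    if cin != c:
        raise ValueError(f"depthwise_conv2d channel mismatch: input has {cin}, weight expects {c}")
    xp = _pad_hw(x.data, pad)
    sn, sc, sh, sw = xp.strides
    oh = (xp.shape[2] - kh) // stride + 1
    ow = (xp.shape[3] - kw) // stride + 1
    view = as_strided(
        xp,
        shape=(n, c, kh, kw, oh, ow),
        strides=(sn, sc, sh, sw, sh * stride, sw * stride),
    )
    cols = np.ascontiguousarray(view)
    out = np.einsum("nchwij,chw->ncij", cols, weight.data, optimize=True)
    if bias is not None:
        out += bias.data.reshape(1, c, 1, 1)

    req = (x.requires_grad or weight.requires_grad or (bias is not None and bias.requires_grad))
    if not (req and is_grad_enabled()):
        return Tensor(out)

    def _bw(g: np.ndarray) -> None:
        if weight.requires_grad:
            weight._accumulate(np.einsum("nchwij,ncij->chw", cols, g, optimize=True))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.einsum("chw,ncij->nchwij", weight.data, g, optimize=True)
            x._accumulate(_col2im(dcols, (n, c, h, w), kh, kw, stride, pad))

    prev = (x, weight) if bias is None else (x, weight, bias)
    return Tensor(out, True, prev, _bw)


def upsample_nearest2d(x: Tensor, scale: int = 2) -> Tensor:
    out = x.data.repeat(scale, axis=2).repeat(scale, axis=3)
    if not (x.requires_grad and is_grad_enabled()):
        return Tensor(out)
    n, c, h, w = x.data.shape

    def _bw(g: np.ndarray) -> None:
        gr = g.reshape(n, c, h, scale, w, scale).sum(axis=(3, 5))
        x._accumulate(gr)

    return Tensor(out, True, (x,), _bw)


def linear(x: Tensor, weight: Tensor, bias: Tensor | None) -> Tensor:
    """x: (N, Din), weight: (Dout, Din), bias: (Dout,)."""
    out = x.data @ weight.data.T
    if bias is not None:
        out = out + bias.data
    req = (x.requires_grad or weight.requires_grad or (bias is not None and bias.requires_grad))
    if not (req and is_grad_enabled()):
        return Tensor(out)

    def _bw(g: np.ndarray) -> None:
        if weight.requires_grad:
            weight._accumulate(g.T @ x.data)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=0))
        if x.requires_grad:
            x._accumulate(g @ weight.data)

    prev = (x, weight) if bias is None else (x, weight, bias)
    return Tensor(out, True, prev, _bw)


def global_avg_pool2d(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C)."""
    return x.mean(axis=(2, 3))


def channel_pool(x: Tensor) -> Tensor:
    """Concatenate mean and max over channels: (N, C, H, W) -> (N, 2, H, W)."""
    from .tensor import concat

    return concat([x.mean(axis=1, keepdims=True), x.max(axis=1, keepdims=True)], axis=1)
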