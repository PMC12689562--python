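"""Structured array ops on :class:`~dmffnet.nn.autograd.Tensor`.

2-D convolution (stride / zero-padding / dilation / channel groups) is
implemented by gathering kernel-tap slices of the padded input and contracting
with ``einsum``; the backward pass scatters tap contributions back with strided
slice-adds.  Bilinear resampling is expressed as a separable pair of sparse
interpolation matrices so its adjoint is the transposed contraction.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .autograd import Tensor

__all__ = ["conv2d", "bilinear_resize", "resize_matrix"]


def _gather_taps(x_pad: np.ndarray, kh: int, kw: int, stride: int, dilation: int,
                 h_out: int, w_out: int) -> np.ndarray:
    """Return tap array of shape (B, C, kh, kw, h_out, w_out) as strided views."""
    b, c = x_pad.shape[:2]
    cols = np.empty((b, c, kh, kw, h_out, w_out), dtype=x_pad.dtype)
    for i in range(kh):
        for j in range(kw):
            hi, wi = i * dilation, j * dilation
            cols[:, :, i, j] = x_pad[:, :, hi:hi + stride * h_out:stride,
                                     wi:wi + stride * w_out:stride]
    return cols


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, *,
           stride: int = 1, padding: int = 0, dilation: int = 1,
           groups: int = 1) -> Tensor:
    """Cross-correlation of NCHW input with OIHW weight.

    ``weight`` has shape (C_out, C_in // groups, kh, kw).  Output spatial size
    follows the usual floor formula; with ``padding = dilation * (k - 1) // 2``
    and stride 1 the spatial size is preserved.
    """
    b, c_in, h, w = x.data.shape
    c_out, c_in_g, kh, kw = weight.data.shape
    if c_in_g * groups != c_in:
        raise ValueError(
            f"conv2d channel mismatch: input has {c_in} channels but weight "
            f"expects {c_in_g * groups} (= {c_in_g} x groups {groups})")
    h_out = (h + 2 * padding - dilation * (kh - 1) - 1) // stride + 1
    w_out = (w + 2 * padding - dilation * (kw - 1) - 1) // stride + 1
    if h_out < 1 or w_out < 1:
        raise ValueError(f"conv2d output collapsed: input {h}x{w}, kernel {kh}x{kw}, "
                         f"dilation {dilation}, padding {padding}")

    x_pad = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = _gather_taps(x_pad, kh, kw, stride, dilation, h_out, w_out)
    # (B, G, Cin/G, kh, kw, Ho, Wo) x (G, Cout/G, Cin/G, kh, kw) -> (B, G, Cout/G, Ho, Wo)
    cols_g = cols.reshape(b, groups, c_in_g, kh, kw, h_out, w_out)
    w_g = weight.data.reshape(groups, c_out // groups, c_in_g, kh, kw)
    out = np.einsum("bgcijhw,gocij->bgohw", cols_g, w_g, optimize=True)
    out = out.reshape(b, c_out, h_out, w_out)
    if bias is not None:
        out = out + bias.data.reshape(1, c_out, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        g_g = g.reshape(b, groups, c_out // groups, h_out, w_out)
        if weight.requires_grad:
            dw = np.einsum("bgohw,bgcijhw->gocij", g_g, cols_g, optimize=True)
            weight._accum(dw.reshape(c_out, c_in_g, kh, kw))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # tap-space cotangent, then strided scatter-add into the padded input
            dcols = np.einsum("bgohw,gocij->bgcijhw", g_g, w_g, optimize=True)
            dcols = dcols.reshape(b, c_in, kh, kw, h_out, w_out)
            dx_pad = np.zeros_like(x_pad)
            for i in range(kh):
                for j in range(kw):
                    hi, wi = i * dilation, j * dilation
                    dx_pad[:, :, hi:hi + stride * h_out:stride,
                           wi:wi + stride * w_out:stride] += dcols[:, :, i, j]
            if padding:
                dx_pad = dx_pad[:, :, padding:-padding, padding:-padding]
            x._accum(dx_pad)

    return Tensor.make(out, parents, backward)


@lru_cache(maxsize=256)
def resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) bilinear interpolation weights, half-pixel centers.

    Non-corner-aligned convention: source coordinate of output pixel ``o`` is
    ``(o + 0.5) * n_in / n_out - 0.5`` clamped to the valid range.
    """
    mat = np.zeros((n_out, n_in))
    scale = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        t = src - lo
        mat[o, lo] += 1.0 - t
        mat[o, hi] += t
    mat.setflags(write=False)
    return mat


def bilinear_resize(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinear resampling of an NCHW tensor to spatial ``size`` (H, W)."""
    h_out, w_out = size
    b, c, h, w = x.data.shape
    ah = resize_matrix(h, h_out)
    aw = resize_matrix(w, w_out)
    out = np.einsum("oh,bchw,pw->bcop", ah, x.data, aw, optimize=True)

    def backward(g):
        x._accum(np.einsum("oh,bcop,pw->bchw", ah, g, aw, optimize=True))

    return Tensor.make(out, (x,), backward)
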