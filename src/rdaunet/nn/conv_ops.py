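"""Differentiable 2-D convolution primitives (NCHW layout).

``conv2d`` lowers to an im2col patch matrix contracted against the kernel
with one batched matmul.  The input gradient of a stride-1 convolution is
itself a convolution — the full correlation of the padded output gradient
with the channel-swapped, spatially flipped kernel — so it reuses the same
im2col/matmul machinery instead of a slow scatter-add; stride-2 1x1
convolutions (the attention gate's downsampler) get a direct strided
scatter, and anything else falls back to a bincount scatter-add.

``conv_transpose2d_2x`` covers the only transposed convolution the network
needs (kernel 2, stride 2, the classic U-Net up-convolution); with
kernel == stride its output blocks do not overlap, so both directions are a
single tensordot.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "conv2d",
    "conv_transpose2d_2x",
    "max_pool2d_2x",
    "upsample_nearest_2x",
]


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N, C*kh*kw, Ho*Wo) patch matrix."""
    n, c, hp, wp = xp.shape
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, kh, kw)
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, ho * wo)
    return np.ascontiguousarray(cols)


def _col_indices(c: int, hp: int, wp: int, kh: int, kw: int, stride: int) -> np.ndarray:
    """Linear indices into a flattened (C, Hp, Wp) volume for each patch cell."""
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    ci = np.repeat(np.arange(c), kh * kw)  # (C*kh*kw,)
    ki = np.tile(np.repeat(np.arange(kh), kw), c)
    kj = np.tile(np.tile(np.arange(kw), kh), c)
    oi = stride * np.repeat(np.arange(ho), wo)  # (Ho*Wo,)
    oj = stride * np.tile(np.arange(wo), ho)
    rows = ki[:, None] + oi[None, :]  # (C*kh*kw, Ho*Wo)
    cols = kj[:, None] + oj[None, :]
    return (ci[:, None] * hp + rows) * wp + cols


def _raw_conv(xp: np.ndarray, w: np.ndarray, stride: int = 1) -> np.ndarray:
    """Valid cross-correlation of a pre-padded input, returns (N, O, Ho, Wo)."""
    n = xp.shape[0]
    o, c, kh, kw = w.shape
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    cols = _im2col(xp, kh, kw, stride)
    out = np.matmul(w.reshape(o, -1), cols)
    return out.reshape(n, o, ho, wo)


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
) -> Tensor:
    """Cross-correlation of ``x`` (N,C,H,W) with ``weight`` (O,C,kh,kw)."""
    n, c, h, w = x.data.shape
    o, c_w, kh, kw = weight.data.shape
    if c != c_w:
        raise ValueError(f"channel mismatch: input has {c}, kernel expects {c_w}")
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = x.data
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    cols = _im2col(xp, kh, kw, stride)  # (N, CKK, L)
    wmat = weight.data.reshape(o, -1)  # (O, CKK)
    out_data = np.matmul(wmat, cols)  # (N, O, L)
    if bias is not None:
        out_data = out_data + bias.data[:, None]
    out_data = out_data.reshape(n, o, ho, wo)

    parents = [x, weight] + ([bias] if bias is not None else [])
    req = any(p.requires_grad for p in parents)
    out = Tensor(out_data, req, parents)
    if not req:
        return out

    def bwd(g: np.ndarray) -> None:
        gmat = g.reshape(n, o, ho * wo)  # (N, O, L)
        if bias is not None and bias.requires_grad:
            bias._accumulate(gmat.sum(axis=(0, 2)))
        if weight.requires_grad:
            dw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0)
            weight._accumulate(dw.reshape(weight.data.shape))
        if x.requires_grad:
            if stride == 1:
                # input gradient = full correlation with the flipped kernel
                gp = np.pad(g, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
                wflip = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
                dxp = _raw_conv(np.ascontiguousarray(gp), np.ascontiguousarray(wflip))
            elif kh == 1 and kw == 1:
                # non-overlapping strided 1x1 taps: direct scatter
                dxp = np.zeros_like(xp)
                dtap = np.tensordot(g, weight.data[:, :, 0, 0], axes=([1], [0]))
                dxp[:, :, ::stride, ::stride] = dtap.transpose(0, 3, 1, 2)
            else:  # pragma: no cover - generic fallback
                dcols = np.matmul(wmat.T, gmat)
                idx = _col_indices(c, hp, wp, kh, kw, stride)
                plane = c * hp * wp
                idx_full = idx.ravel()[None, :] + (np.arange(n) * plane)[:, None]
                dxp = np.bincount(
                    idx_full.ravel(),
                    weights=dcols.reshape(n, -1).astype(np.float64).ravel(),
                    minlength=n * plane,
                ).reshape(xp.shape).astype(x.data.dtype)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    out._backward = bwd
    return out


def conv_transpose2d_2x(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Transposed convolution, kernel 2, stride 2: doubles spatial size.

    ``weight`` has shape (C_in, C_out, 2, 2), matching the convention that a
    transposed convolution is the adjoint of a forward stride-2 convolution.
    """
    n, c, h, w = x.data.shape
    c_w, o, kh, kw = weight.data.shape
    if c != c_w or (kh, kw) != (2, 2):
        raise ValueError("conv_transpose2d_2x expects weight (C_in, C_out, 2, 2)")
    # non-overlapping 2x2 output blocks: (N,H,W,O,kh,kw) -> (N,O,2H,2W)
    blocks = np.tensordot(x.data, weight.data, axes=([1], [0]))
    out_data = np.ascontiguousarray(
        blocks.transpose(0, 3, 1, 4, 2, 5)
    ).reshape(n, o, 2 * h, 2 * w)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]

    parents = [x, weight] + ([bias] if bias is not None else [])
    req = any(p.requires_grad for p in parents)
    out = Tensor(out_data, req, parents)
    if not req:
        return out

    def bwd(g: np.ndarray) -> None:
        gb = g.reshape(n, o, h, 2, w, 2)  # (N, O, H, kh, W, kw)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        gq = np.ascontiguousarray(gb.transpose(0, 2, 4, 1, 3, 5))  # (N,H,W,O,kh,kw)
        if weight.requires_grad:
            dw = np.tensordot(x.data, gq, axes=([0, 2, 3], [0, 1, 2]))  # (C,O,kh,kw)
            weight._accumulate(dw)
        if x.requires_grad:
            dx = np.tensordot(gq, weight.data, axes=([3, 4, 5], [1, 2, 3]))  # (N,H,W,C)
            x._accumulate(np.ascontiguousarray(dx.transpose(0, 3, 1, 2)))

    out._backward = bwd
    return out


def max_pool2d_2x(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; ties resolve to the first maximum."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2d_2x needs even spatial size, got {h}x{w}")
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    quad = np.ascontiguousarray(blocks.transpose(0, 1, 2, 4, 3, 5)).reshape(
        n, c, h // 2, w // 2, 4
    )
    arg = quad.argmax(axis=-1)
    out_data = np.take_along_axis(quad, arg[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, x.requires_grad, (x,))
    if x.requires_grad:

        def bwd(g: np.ndarray) -> None:
            dquad = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
            np.put_along_axis(dquad, arg[..., None], g[..., None], axis=-1)
            dx = np.ascontiguousarray(
                dquad.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            ).reshape(n, c, h, w)
            x._accumulate(dx)

        out._backward = bwd
    return out


def upsample_nearest_2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling; adjoint is 2x2 block summation."""
    n, c, h, w = x.data.shape
    out = Tensor(x.data.repeat(2, axis=2).repeat(2, axis=3), x.requires_grad, (x,))
    if x.requires_grad:
        out._backward = lambda g: x._accumulate(
            g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
        )
    return out
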