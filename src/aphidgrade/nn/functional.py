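"""Spatial ops (convolution, pooling, padding, upsampling) for NCHW tensors.

Convolution is implemented by im2col + one BLAS matmul; the backward pass
re-uses the cached column matrix for the weight gradient and folds the input
gradient back with a loop over the kernel footprint (cheap: k*k strided adds).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, is_grad_enabled

__all__ = ["pad2d", "conv2d", "max_pool2d", "avg_pool2d", "global_avg_pool",
           "upsample2x", "layer_norm"]


def pad2d(x: Tensor, pad: int | tuple[int, int]) -> Tensor:
    ph, pw = (pad, pad) if isinstance(pad, int) else pad
    if ph == 0 and pw == 0:
        return x
    out_data = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))

    def bw(g):
        x._accum(g[:, :, ph:g.shape[2] - ph, pw:g.shape[3] - pw])

    return Tensor._make(out_data, (x,), bw)


def _im2col(xd: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    # (B, C, H, W) -> (B, Ho, Wo, C*kh*kw)
    win = sliding_window_view(xd, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    # win: (B, C, Ho, Wo, kh, kw)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int | tuple[int, int] = 0) -> Tensor:
    """2-D cross-correlation. weight: (O, C, kh, kw)."""
    xp = pad2d(x, padding)
    B, C, H, W = xp.shape
    O, Cw, kh, kw = weight.shape
    if Cw != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Cw}")
    if H < kh or W < kw:
        raise ValueError("conv2d input smaller than kernel")
    Ho = (H - kh) // stride + 1
    Wo = (W - kw) // stride + 1
    cols6 = _im2col(xp.data, kh, kw, stride)        # (B, Ho, Wo, C, kh, kw)
    cols = cols6.reshape(B * Ho * Wo, C * kh * kw)
    wmat = weight.data.reshape(O, -1)
    out = cols @ wmat.T                             # (B*Ho*Wo, O)
    if bias is not None:
        out = out + bias.data
    out_data = out.reshape(B, Ho, Wo, O).transpose(0, 3, 1, 2)
    out_data = np.ascontiguousarray(out_data)

    if not is_grad_enabled():
        return Tensor(out_data)

    def bw(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, O)
        if weight.requires_grad:
            gw = gmat.T @ cols
            weight._accum(gw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(gmat.sum(axis=0))
        if xp.requires_grad:
            dcols = (gmat @ wmat).reshape(B, Ho, Wo, C, kh, kw)
            dx = np.zeros((B, C, H, W), dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    dx[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += \
                        dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            xp._accum(dx)

    parents = (xp, weight) if bias is None else (xp, weight, bias)
    return Tensor._make(out_data, parents, bw)


def max_pool2d(x: Tensor, kernel: int, stride: int | None = None,
               padding: int = 0) -> Tensor:
    stride = stride or kernel
    xp = pad2d(x, padding) if padding else x
    B, C, H, W = xp.shape
    Ho = (H - kernel) // stride + 1
    Wo = (W - kernel) // stride + 1
    win = sliding_window_view(xp.data, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    out_data = win.max(axis=(4, 5))

    def bw(g):
        mask = (win == out_data[..., None, None])
        counts = mask.sum(axis=(4, 5), keepdims=True)
        contrib = mask * (g[..., None, None] / counts)
        dx = np.zeros((B, C, H, W), dtype=np.float32)
        for i in range(kernel):
            for j in range(kernel):
                dx[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += \
                    contrib[:, :, :, :, i, j]
        xp._accum(dx)

    return Tensor._make(np.ascontiguousarray(out_data), (xp,), bw)


def avg_pool2d(x: Tensor, kernel: int, stride: int | None = None) -> Tensor:
    stride = stride or kernel
    B, C, H, W = x.shape
    Ho = (H - kernel) // stride + 1
    Wo = (W - kernel) // stride + 1
    win = sliding_window_view(x.data, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    out_data = win.mean(axis=(4, 5))
    inv = 1.0 / (kernel * kernel)

    def bw(g):
        dx = np.zeros((B, C, H, W), dtype=np.float32)
        for i in range(kernel):
            for j in range(kernel):
                dx[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += g * inv
        x._accum(dx)

    return Tensor._make(np.ascontiguousarray(out_data), (x,), bw)


def global_avg_pool(x: Tensor) -> Tensor:
    """(B, C, H, W) -> (B, C) spatial mean."""
    return x.mean(axis=(2, 3))


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling; backward sums 2x2 blocks."""
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def bw(g):
        B, C, H, W = g.shape
        x._accum(g.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5)))

    return Tensor._make(out_data, (x,), bw)


def batch_norm(x: Tensor, weight: Tensor, bias: Tensor, axes: tuple[int, ...],
               shape, eps: float = 1e-5) -> Tensor:
    """Fused batch normalisation over ``axes`` with affine parameters;
    ``shape`` broadcasts the per-channel parameters."""
    n = int(np.prod([x.data.shape[a] for a in axes]))
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    w = weight.data.reshape(shape)
    out_data = (xhat * w + bias.data.reshape(shape)).astype(np.float32)

    def bw(g):
        if weight.requires_grad:
            weight._accum((g * xhat).sum(axis=axes).reshape(weight.data.shape))
        if bias.requires_grad:
            bias._accum(g.sum(axis=axes).reshape(bias.data.shape))
        if x.requires_grad:
            gx = g * w
            dx = inv * (gx - gx.mean(axis=axes, keepdims=True)
                        - xhat * (gx * xhat).mean(axis=axes, keepdims=True))
            x._accum(dx.astype(np.float32))

    return Tensor._make(out_data, (x, weight, bias), bw)


def layer_norm(x: Tensor, weight: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis with affine parameters."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = xhat * weight.data + bias.data
    N = x.data.shape[-1]

    def bw(g):
        if weight.requires_grad:
            weight._accum((g * xhat).reshape(-1, N).sum(axis=0))
        if bias.requires_grad:
            bias._accum(g.reshape(-1, N).sum(axis=0))
        if x.requires_grad:
            gx = g * weight.data
            dx = inv * (gx - gx.mean(axis=-1, keepdims=True)
                        - xhat * (gx * xhat).mean(axis=-1, keepdims=True))
            x._accum(dx.astype(np.float32))

    return Tensor._make(out_data.astype(np.float32), (x, weight, bias), bw)
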