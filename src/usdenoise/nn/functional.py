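"""Differentiable array operations used by the denoising networks.

All functions take and return :class:`~usdenoise.nn.tensor.Tensor` in
``(N, C, H, W)`` layout and register their own backward closures.
Convolution is computed by im2col (``sliding_window_view`` then one
contiguous copy) plus matrix multiplication; the column matrix is cached
on the tape and reused by the backward pass.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = [
    "conv2d", "prelu", "relu", "max_pool2x2", "upsample_nearest2x",
    "concat_channels", "mse_loss",
]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1,
           padding: int = 1) -> Tensor:
    """2-D cross-correlation with zero padding.

    ``x``: (N, C, H, W); ``weight``: (O, C, kh, kw); ``bias``: (O,).
    """
    n, c, h, w = x.data.shape
    o, c_w, kh, kw = weight.data.shape
    if c != c_w:
        raise ValueError(f"channel mismatch: input has {c}, kernel expects {c_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    # im2col once; the matrix is cached and reused by the backward pass
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)
                                ).reshape(n * ho * wo, c * kh * kw)
    wmat = weight.data.reshape(o, -1)
    y = (cols @ wmat.T).reshape(n, ho, wo, o).transpose(0, 3, 1, 2)
    y = y + bias.data[None, :, None, None]

    def bw(g, x=x, weight=weight, bias=bias, cols=cols, wmat=wmat):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, o)
        if bias.requires_grad or bias._parents:
            bias._accumulate(gmat.sum(axis=0))
        if weight.requires_grad or weight._parents:
            weight._accumulate((gmat.T @ cols).reshape(weight.data.shape))
        if x.requires_grad or x._parents:
            gcols = (gmat @ wmat).reshape(n, ho, wo, c, kh, kw)
            gcols = gcols.transpose(0, 3, 4, 5, 1, 2)   # (N, C, kh, kw, Ho, Wo)
            gxp = np.zeros((n, c, h + 2 * padding, w + 2 * padding), dtype=g.dtype)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + stride * ho:stride,
                        j:j + stride * wo:stride] += gcols[:, :, i, j]
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    return Tensor._node(y, (x, weight, bias), bw)


def prelu(x: Tensor, slope: Tensor) -> Tensor:
    """Parametric ReLU: x where x > 0, slope*x where x <= 0.

    ``slope`` has shape (C,) (one learnable slope per channel) or (1,)
    (a single slope shared across channels).
    """
    s = slope.data[None, :, None, None]
    pos = x.data > 0
    y = np.where(pos, x.data, s * x.data)

    def bw(g, x=x, slope=slope, pos=pos):
        if slope.requires_grad or slope._parents:
            gs_full = np.where(pos, 0.0, g * x.data)
            if slope.data.shape[0] == 1:
                slope._accumulate(np.array([gs_full.sum()]))
            else:
                slope._accumulate(gs_full.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            x._accumulate(np.where(pos, g, g * slope.data[None, :, None, None]))

    return Tensor._node(y, (x, slope), bw)


def relu(x: Tensor) -> Tensor:
    """max(0, x): the degenerate PReLU with zero negative slope."""
    pos = x.data > 0
    y = np.where(pos, x.data, 0.0)

    def bw(g, x=x, pos=pos):
        if x.requires_grad or x._parents:
            x._accumulate(np.where(pos, g, 0.0))

    return Tensor._node(y, (x,), bw)


def max_pool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; H and W must be even."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("max_pool2x2 requires even spatial dims")
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    flat = r.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def bw(g, x=x, idx=idx):
        if x.requires_grad or x._parents:
            gflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
            np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
            gx = gflat.reshape(n, c, h // 2, w // 2, 2, 2) \
                      .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
            x._accumulate(gx)

    return Tensor._node(y, (x,), bw)


def upsample_nearest2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    y = x.data.repeat(2, axis=2).repeat(2, axis=3)
    n, c, h, w = x.data.shape

    def bw(g, x=x):
        if x.requires_grad or x._parents:
            x._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return Tensor._node(y, (x,), bw)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate two feature maps along the channel axis."""
    ca = a.data.shape[1]
    y = np.concatenate([a.data, b.data], axis=1)

    def bw(g, a=a, b=b, ca=ca):
        if a.requires_grad or a._parents:
            a._accumulate(g[:, :ca])
        if b.requires_grad or b._parents:
            b._accumulate(g[:, ca:])

    return Tensor._node(y, (a, b), bw)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error against a constant target array."""
    t = Tensor(target)
    return (pred - t).square().mean()
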