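"""Non-local means denoising.

Each output pixel is a weighted average over the pixels of its search
window, with weights

    w(i, j) = exp( -||P_i - P_j||^2 / h^2 ),

where ``P_i`` is the square patch centred on pixel ``i`` (images are
reflect-padded for patches that overhang the border), ``||.||^2`` is the
plain sum of squared differences over the patch, and the weights at
every pixel are normalised to sum to one.  The search window is clipped
at the image boundary.  The implementation vectorises over window
offsets; tests validate it against a literal double-loop evaluation of
the same definition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .phantom import GrayImage

__all__ = ["NLMeansParams", "nl_means"]

log = logging.getLogger(__name__)


@dataclass
class NLMeansParams:
    """patch_size and search_window are odd side lengths; h is the
    filtering strength on the pixel-intensity scale."""

    patch_size: int = 5
    search_window: int = 13
    h: float = 100.0

    def __post_init__(self):
        if self.patch_size < 3 or self.patch_size % 2 == 0:
            raise ValueError("patch_size must be an odd integer >= 3")
        if self.search_window % 2 == 0 or self.search_window < self.patch_size:
            raise ValueError("search_window must be odd and >= patch_size")
        if self.h <= 0:
            raise ValueError("filtering strength h must be > 0")

    @classmethod
    def for_noise_sigma(cls, sigma_px: float, patch_size: int = 5,
                        search_window: int = 13) -> "NLMeansParams":
        """Filtering strength matched to the noise level: h^2 is set to
        2 sigma^2 p^2 (twice the expected patch SSD between two noisy
        copies of the same underlying patch)."""
        h = max(np.sqrt(2.0) * sigma_px * patch_size, 1e-6)
        return cls(patch_size=patch_size, search_window=search_window, h=h)


def nl_means(noisy: GrayImage | np.ndarray,
             params: NLMeansParams | None = None) -> GrayImage:
    """Denoise one grayscale image by non-local patch averaging.

    Deterministic, shape-preserving; output stays in the valid range
    (it is a convex combination of input pixels).
    """
    params = params or NLMeansParams()
    img = noisy if isinstance(noisy, GrayImage) else GrayImage(noisy)
    a = img.pixels.astype(np.float64)
    h_img, w_img = a.shape

    win = params.search_window
    if win > min(h_img, w_img):
        log.warning("image %dx%d smaller than search window %d; "
                    "using whole-image window", h_img, w_img, win)
        win = min(h_img, w_img) if min(h_img, w_img) % 2 == 1 \
            else min(h_img, w_img) - 1
    wr = win // 2
    p = params.patch_size
    pr = p // 2
    h2 = params.h ** 2

    apad = np.pad(a, pr, mode="reflect")
    num = np.zeros_like(a)
    den = np.zeros_like(a)

    for dy in range(-wr, wr + 1):
        for dx in range(-wr, wr + 1):
            # region of pixels i for which i + (dy, dx) is inside the image
            iy0, iy1 = max(0, -dy), h_img - max(0, dy)
            ix0, ix1 = max(0, -dx), w_img - max(0, dx)
            if iy0 >= iy1 or ix0 >= ix1:
                continue
            # padded-coordinate blocks covering the patches of that region
            blk = apad[iy0:iy1 + 2 * pr, ix0:ix1 + 2 * pr]
            blk_s = apad[iy0 + dy:iy1 + dy + 2 * pr,
                         ix0 + dx:ix1 + dx + 2 * pr]
            d2 = (blk - blk_s) ** 2
            ssd = sliding_window_view(d2, (p, p)).sum(axis=(-1, -2))
            w = np.exp(-ssd / h2)
            num[iy0:iy1, ix0:ix1] += w * a[iy0 + dy:iy1 + dy,
                                           ix0 + dx:ix1 + dx]
            den[iy0:iy1, ix0:ix1] += w
    out = num / den
    return GrayImage(out, bit_depth=img.bit_depth)
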