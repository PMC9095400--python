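"""Image-quality measures: MSE, PSNR and SSIM.

PSNR is defined against the peak intensity of an ``n``-bit image,

    PSNR = 10 * log10( (2**n - 1)**2 / MSE )   [dB],

with a +infinity sentinel when MSE is zero.  SSIM is the single-statistic
structural similarity

    SSIM(X, Y) = (2 u_X u_Y + C1)(2 cov_XY + C2)
                 / ((u_X^2 + u_Y^2 + C1)(sigma_X^2 + sigma_Y^2 + C2)),

computed either globally over the whole image (the default — the formula
as written, one value per pair) or averaged over non-overlapping windows.
Variances and covariances use the population (divide-by-N) convention.
Default constants are the field-standard C1 = (0.01 L)^2,
C2 = (0.03 L)^2 with L = 2**n - 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import GrayImage

__all__ = ["MetricReport", "mse", "psnr", "ssim", "default_ssim_constants",
           "report"]

PSNR_INF = np.inf


def _pixels(img) -> np.ndarray:
    if isinstance(img, GrayImage):
        return img.pixels
    return np.asarray(img, dtype=np.float64)


def _check_shapes(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")


@dataclass
class MetricReport:
    """Per-image-pair quality summary."""

    mse: float
    psnr_db: float
    ssim: float
    c1: float
    c2: float
    bit_depth: int = 8

    def to_dict(self) -> dict:
        return {
            "mse": self.mse,
            "psnr_db": "inf" if np.isinf(self.psnr_db) else self.psnr_db,
            "ssim": self.ssim,
            "C1": self.c1,
            "C2": self.c2,
            "bit_depth": self.bit_depth,
        }


def mse(x, y) -> float:
    """Mean squared error between two equal-shape images."""
    xp, yp = _pixels(x), _pixels(y)
    _check_shapes(xp, yp)
    return float(np.mean((xp - yp) ** 2))


def psnr(x, y, n: int = 8) -> float:
    """Peak signal-to-noise ratio in dB for ``n``-bit images.

    Returns ``inf`` when the images are identical (MSE = 0).
    """
    if n < 1:
        raise ValueError("bit depth must be >= 1")
    err = mse(x, y)
    if err == 0.0:
        return PSNR_INF
    peak = 2 ** n - 1
    return float(10.0 * np.log10(peak ** 2 / err))


def default_ssim_constants(n: int = 8) -> tuple[float, float]:
    """(C1, C2) = ((0.01 L)^2, (0.03 L)^2), L the peak intensity."""
    peak = 2 ** n - 1
    return (0.01 * peak) ** 2, (0.03 * peak) ** 2


def _ssim_stat(x: np.ndarray, y: np.ndarray, c1: float, c2: float) -> float:
    ux, uy = x.mean(), y.mean()
    vx, vy = x.var(), y.var()          # population convention
    cov = ((x - ux) * (y - uy)).mean()
    return float((2 * ux * uy + c1) * (2 * cov + c2)
                 / ((ux ** 2 + uy ** 2 + c1) * (vx + vy + c2)))


def ssim(x, y, c1: float | None = None, c2: float | None = None,
         mode: str = "global", window: int = 8, n: int = 8) -> float:
    """Structural similarity between two images.

    ``mode="global"`` evaluates the formula once over the whole image;
    ``mode="windowed"`` averages it over non-overlapping ``window`` x
    ``window`` tiles (ragged edge tiles included as-is).
    """
    if c1 is None or c2 is None:
        d1, d2 = default_ssim_constants(n)
        c1 = d1 if c1 is None else c1
        c2 = d2 if c2 is None else c2
    if c1 <= 0 or c2 <= 0:
        raise ValueError("C1 and C2 must be positive")
    xp, yp = _pixels(x), _pixels(y)
    _check_shapes(xp, yp)
    if mode == "global":
        return _ssim_stat(xp, yp, c1, c2)
    if mode != "windowed":
        raise ValueError(f"unknown mode {mode!r}")
    h, w = xp.shape
    vals = []
    for i in range(0, h, window):
        for j in range(0, w, window):
            vals.append(_ssim_stat(xp[i:i + window, j:j + window],
                                   yp[i:i + window, j:j + window], c1, c2))
    return float(np.mean(vals))


def report(x, y, n: int = 8, c1: float | None = None,
           c2: float | None = None, mode: str = "global") -> MetricReport:
    """Full MetricReport (MSE + PSNR + SSIM) for one image pair."""
    d1, d2 = default_ssim_constants(n)
    c1 = d1 if c1 is None else c1
    c2 = d2 if c2 is None else c2
    return MetricReport(
        mse=mse(x, y),
        psnr_db=psnr(x, y, n=n),
        ssim=ssim(x, y, c1=c1, c2=c2, mode=mode, n=n),
        c1=c1, c2=c2, bit_depth=n,
    )
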