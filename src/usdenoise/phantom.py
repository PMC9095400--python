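"""Synthetic ultrasound-like phantom generation and noise injection.

A phantom mimics the appearance of an ovarian-cyst B-mode scan: a dark
(hypoechoic) elliptical cyst embedded in brighter tissue-echo texture,
with a few small bright floaters inside the cyst.  Phantoms are the
ground-truth "clean" images against which denoisers are trained and
scored; no real patient data is involved.

The noise decomposition follows the convention

    a + e = b

where ``a`` is the noisy image, ``b`` the clean image and ``e`` the
correction that restores the clean image (so ``e = b - a``).  Noise can
be additive Gaussian or multiplicative speckle; after the noisy image is
clipped to the valid intensity range, ``e`` is recomputed as ``b - a``
so the identity holds exactly for every emitted sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "GrayImage", "PhantomSpec", "NoiseSpec", "NoisySample",
    "SIGMA_TO_PIXEL", "generate_phantom", "add_noise", "make_dataset",
]

#: Benchmark noise levels are quoted as dimensionless standard deviations
#: (0.5 .. 2.5); this factor maps them to 8-bit pixel units, so the five
#: levels span sigma_px = 12.75 .. 63.75 (visually light to heavy noise).
SIGMA_TO_PIXEL = 25.5


@dataclass
class GrayImage:
    """A 2-D grayscale image with an associated bit depth.

    ``pixels`` are float during computation; ``quantized`` flags that
    every value is an integer-valued float in ``[0, 2**bit_depth - 1]``.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    quantized: bool = False

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size < 1:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if self.quantized:
            lo, hi = 0, 2 ** self.bit_depth - 1
            if self.pixels.min() < lo or self.pixels.max() > hi:
                raise ValueError(f"quantized image outside [{lo}, {hi}]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def peak(self) -> float:
        """Largest representable intensity, 2**n - 1."""
        return float(2 ** self.bit_depth - 1)

    def quantize(self) -> "GrayImage":
        """Round and clip to the valid range."""
        q = np.clip(np.rint(self.pixels), 0, self.peak)
        return GrayImage(q, bit_depth=self.bit_depth, quantized=True)


@dataclass
class PhantomSpec:
    """Geometry and intensity description of one synthetic phantom."""

    size: tuple[int, int] = (64, 64)
    cyst_center: tuple[float, float] | None = None   # (row, col); None = image centre
    cyst_semiaxes: tuple[float, float] = (18.0, 14.0)
    cyst_mean: float = 40.0
    background_mean: float = 160.0
    texture_sd: float = 20.0
    correlation_length: float = 1.5
    n_spots: int = 3
    spot_intensity: float = 220.0
    spot_radius: float = 1.5
    seed: int = 0

    def __post_init__(self):
        h, w = self.size
        if h < 1 or w < 1:
            raise ValueError("phantom size must be positive")
        if not self.cyst_mean < self.background_mean:
            raise ValueError("cyst must be hypoechoic: cyst_mean < background_mean")
        cy, cx = self.center
        ay, ax = self.cyst_semiaxes
        if ay <= 0 or ax <= 0:
            raise ValueError("semi-axes must be positive")
        if cy - ay < 0 or cy + ay > h - 1 or cx - ax < 0 or cx + ax > w - 1:
            raise ValueError("cyst ellipse must lie fully inside the image")

    @property
    def center(self) -> tuple[float, float]:
        if self.cyst_center is not None:
            return self.cyst_center
        h, w = self.size
        return ((h - 1) / 2.0, (w - 1) / 2.0)


@dataclass
class NoiseSpec:
    """Noise model and level.

    ``sigma`` is on the dimensionless benchmark scale; the pixel-scale
    standard deviation is ``sigma * scale`` (``scale`` defaults to
    :data:`SIGMA_TO_PIXEL` for additive noise).  For multiplicative
    speckle, ``sigma`` scales the relative fluctuation directly:
    a = b + b*eta with eta ~ N(0, (sigma*mult_scale)^2).
    """

    model: str = "multiplicative_speckle"
    sigma: float = 1.0
    seed: int = 0
    scale: float = SIGMA_TO_PIXEL
    mult_scale: float = 0.2

    def __post_init__(self):
        if self.model not in ("additive_gaussian", "multiplicative_speckle"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def sigma_px(self) -> float:
        """Pixel-scale standard deviation (additive model)."""
        return self.sigma * self.scale


@dataclass
class NoisySample:
    """(noisy a, clean b, noise e) with a + e = b exact."""

    noisy: GrayImage
    clean: GrayImage
    noise: np.ndarray
    noise_spec: NoiseSpec

    def __post_init__(self):
        if not (self.noisy.pixels.shape == self.clean.pixels.shape
                == self.noise.shape):
            raise ValueError("a, b, e must share one shape")
        resid = self.noisy.pixels + self.noise - self.clean.pixels
        if np.abs(resid).max() > np.finfo(np.float64).eps * self.clean.peak:
            raise ValueError("a + e = b violated beyond one ulp")


def _ellipse_mask(shape, center, semiaxes) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    cy, cx = center
    ay, ax = semiaxes
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> GrayImage:
    """Render one phantom: textured background, hypoechoic cyst, floaters.

    Deterministic for a fixed ``spec.seed``; the output is quantized to
    the 8-bit range.  Background texture is smoothed white noise
    (Gaussian blur of i.i.d. noise, renormalised to ``texture_sd``),
    a simple stand-in for tissue speckle texture.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size

    texture = rng.normal(0.0, 1.0, size=(h, w))
    if spec.correlation_length > 0:
        texture = gaussian_filter(texture, spec.correlation_length, mode="reflect")
        sd = texture.std()
        if sd > 0:
            texture /= sd
    texture *= spec.texture_sd
    # bounded texture keeps "cyst interior stays dark" exact, not just probable
    texture = np.clip(texture, -3.0 * spec.texture_sd, 3.0 * spec.texture_sd)

    mask = _ellipse_mask((h, w), spec.center, spec.cyst_semiaxes)
    img = np.where(mask, spec.cyst_mean, spec.background_mean) + texture

    # bright floaters: small Gaussian bumps, confined to the cyst interior
    cy, cx = spec.center
    ay, ax = spec.cyst_semiaxes
    yy, xx = np.mgrid[0:h, 0:w]
    spots = np.zeros((h, w))
    for _ in range(spec.n_spots):
        # sample well inside the ellipse so floaters sit in the dark area
        r = np.sqrt(rng.uniform(0.0, 0.55))
        th = rng.uniform(0.0, 2 * np.pi)
        sy, sx = cy + r * ay * np.sin(th), cx + r * ax * np.cos(th)
        bump = spec.spot_intensity * np.exp(
            -((yy - sy) ** 2 + (xx - sx) ** 2) / (2.0 * spec.spot_radius ** 2))
        spots = np.maximum(spots, bump)
    img = np.where(mask, np.maximum(img, spots), img)
    return GrayImage(img).quantize()


def add_noise(clean: GrayImage, noise: NoiseSpec) -> NoisySample:
    """Corrupt a clean image and return the exact (a, b, e) triple.

    additive_gaussian:       a = b + g,      g ~ N(0, sigma_px^2) i.i.d.
    multiplicative_speckle:  a = b + b*eta,  eta ~ N(0, (sigma*mult_scale)^2)

    The noisy image is clipped to the valid range, then e is recomputed
    as b - a, so ``a + e = b`` holds exactly even at clipped pixels.
    """
    if not clean.quantized:
        clean = clean.quantize()
    rng = np.random.default_rng(noise.seed)
    b = clean.pixels
    if noise.sigma == 0:
        a = b.copy()
    elif noise.model == "additive_gaussian":
        a = b + rng.normal(0.0, noise.sigma_px, size=b.shape)
    else:
        eta = rng.normal(0.0, noise.sigma * noise.mult_scale, size=b.shape)
        a = b + b * eta
    a = np.clip(a, 0.0, clean.peak)
    e = b - a
    return NoisySample(
        noisy=GrayImage(a, bit_depth=clean.bit_depth),
        clean=clean,
        noise=e,
        noise_spec=noise,
    )


def make_dataset(n_images: int, noise: NoiseSpec, seed: int = 0,
                 phantom_spec: PhantomSpec | None = None,
                 val_fraction: float = 0.2,
                 jitter: bool = True):
    """Generate ``n_images`` independent noisy/clean pairs plus a split.

    Per-sample seeds are spawned deterministically from ``seed``.  With
    ``jitter`` the phantom geometry (cyst size, position, contrast,
    floater count) varies between samples around ``phantom_spec``.

    Returns ``(samples, train_idx, val_idx)`` with disjoint index lists
    (last ``val_fraction`` of samples are validation).
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    base = phantom_spec or PhantomSpec()
    master = np.random.default_rng(seed)
    sample_seeds = master.integers(0, 2 ** 31 - 1, size=(n_images, 2))

    samples = []
    h, w = base.size
    for k in range(n_images):
        pseed, nseed = int(sample_seeds[k, 0]), int(sample_seeds[k, 1])
        spec = replace(base, seed=pseed)
        if jitter:
            jrng = np.random.default_rng(pseed)
            ay = jrng.uniform(0.6, 1.1) * base.cyst_semiaxes[0]
            ax = jrng.uniform(0.6, 1.1) * base.cyst_semiaxes[1]
            ay = min(ay, (h - 3) / 2.0)
            ax = min(ax, (w - 3) / 2.0)
            cy = jrng.uniform(ay + 1, h - 2 - ay)
            cx = jrng.uniform(ax + 1, w - 2 - ax)
            spec = replace(
                spec,
                cyst_center=(cy, cx),
                cyst_semiaxes=(ay, ax),
                cyst_mean=jrng.uniform(25.0, 60.0),
                background_mean=jrng.uniform(130.0, 190.0),
                n_spots=int(jrng.integers(0, base.n_spots + 1)),
            )
        clean = generate_phantom(spec)
        samples.append(add_noise(clean, replace(noise, seed=nseed)))

    n_val = int(round(n_images * val_fraction))
    n_train = n_images - n_val
    train_idx = list(range(n_train))
    val_idx = list(range(n_train, n_images))
    return samples, train_idx, val_idx
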