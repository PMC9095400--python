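"""Grayscale image file I/O (PNG/TIFF, 8-bit canonical).

write/read round-trips are bit-exact for 8-bit grayscale PNG.
Multi-channel inputs are converted to luminance with a logged warning;
16-bit TIFF is accepted and rescaled to 8-bit with a logged factor.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .phantom import GrayImage

__all__ = ["read_image", "write_image"]

log = logging.getLogger(__name__)

# ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


def read_image(path) -> GrayImage:
    """Load a PNG or TIFF as an 8-bit :class:`GrayImage`."""
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        log.warning("%s has %d channels; converting to luminance",
                    path.name, arr.shape[2])
        arr = arr.astype(np.float64) @ _LUMA
    elif arr.ndim != 2:
        raise IOError(f"{path}: unsupported image rank {arr.ndim}")
    if arr.dtype == np.uint16:
        log.warning("%s is 16-bit; rescaling by 1/257 to 8-bit", path.name)
        arr = arr.astype(np.float64) / 257.0
    return GrayImage(np.asarray(arr, dtype=np.float64)).quantize()


def write_image(image: GrayImage, path) -> None:
    """Store a quantized image as 8-bit grayscale PNG/TIFF."""
    if not image.quantized:
        image = image.quantize()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, image.pixels.astype(np.uint8))
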