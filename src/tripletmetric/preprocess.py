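"""Image enhancement and normalization applied before feature extraction.

Two steps: global 256-bin histogram equalization (the classical contrast
enhancement for grayscale radiographs) and a resize-plus-rescale that brings
any grayscale image to the square ``[0, 1]``-valued array the embedding
network consumes.  Downscaling by an integer factor is exact block averaging;
other geometry changes use antialiased bilinear resampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import downscale_local_mean, resize

__all__ = ["EnhancedImage", "equalize_histogram", "resize_normalize"]


@dataclass
class EnhancedImage:
    pixels: np.ndarray
    source_id: str = ""


def equalize_histogram(image, source_id: str = "") -> EnhancedImage:
    """Global histogram equalization over 256 intensity levels.

    The output level of input level ``v`` is
    ``round((cdf(v) - cdf_min) / (n_pixels - cdf_min) * 255)`` where ``cdf``
    is the cumulative 256-bin histogram and ``cdf_min`` its value at the
    lowest occupied level.  The map is monotone non-decreasing, so the
    ranking of distinct input intensities is preserved, and it is idempotent
    to within one intensity level.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("image is empty")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    levels = np.clip(np.round(img).astype(int), 0, 255)
    hist = np.bincount(levels.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    cdf_min = cdf[np.flatnonzero(hist)[0]]
    n = levels.size
    if n == cdf_min:  # constant image: map everything onto itself
        mapped = np.arange(256)
    else:
        mapped = np.round((cdf - cdf_min) / (n - cdf_min) * 255.0).astype(int)
    return EnhancedImage(pixels=mapped[levels].astype(np.uint8), source_id=source_id)


def resize_normalize(image, target: int, source_id: str = "") -> EnhancedImage:
    """Resize a grayscale image to ``target x target`` and rescale
    intensities from [0, 255] to real values in [0, 1]."""
    if target < 32:
        raise ValueError("target must be >= 32")
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("image is empty")
    h, w = img.shape
    if (h, w) == (target, target):
        out = img
    elif h == w and h % target == 0:
        f = h // target
        out = downscale_local_mean(img, (f, f))
    else:
        out = resize(
            img,
            (target, target),
            order=1,
            anti_aliasing=(h > target or w > target),
            preserve_range=True,
        )
    return EnhancedImage(pixels=np.clip(out / 255.0, 0.0, 1.0), source_id=source_id)
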