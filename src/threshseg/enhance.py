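"""Contrast enhancement by global histogram equalization.

Radiographs with low contrast or uneven exposure lose the clean bimodal
(hand vs. background) histogram shape that threshold selection relies on;
classical histogram equalization restores it. The exact discrete mapping is

    out(v) = round(255 * (cdf(v) - cdf_min) / (N - cdf_min))

with ``cdf`` the cumulative pixel count and ``cdf_min`` the count of the
lowest occupied bin — dialects of this formula differ, so it is pinned here
to keep downstream labels bit-reproducible. Global (whole-image)
equalization only; CLAHE and other adaptive variants are out of scope.
"""

from __future__ import annotations

import numpy as np

__all__ = ["equalize_histogram"]


def _check_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2 or img.size == 0:
        raise ValueError(f"expected a non-empty 2-D image, got shape {img.shape}")
    if img.dtype != np.uint8:
        if np.any((img < 0) | (img > 255)):
            raise ValueError("gray image values must lie in [0, 255]")
        img = img.astype(np.uint8)
    return img


def equalize_histogram(img: np.ndarray) -> np.ndarray:
    """Globally equalize an 8-bit grayscale image.

    The mapping is monotone non-decreasing, so pixel rank order is preserved
    up to ties. A constant image is returned unchanged (its one-level CDF
    admits no spread).
    """
    img = _check_gray(img)
    hist = np.bincount(img.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    n = cdf[-1]
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    if n == cdf_min:  # single occupied bin
        return img.copy()
    lut = np.rint(255.0 * (cdf - cdf_min) / float(n - cdf_min))
    return np.clip(lut, 0, 255).astype(np.uint8)[img]
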