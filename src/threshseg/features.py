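"""Per-image intensity features for threshold prediction.

Each (enhanced) image is summarized by its normalized 256-bin gray-level
histogram plus the mean and population variance of its pixels — a 258-long
vector. These are the only inputs the classifiers see; no texture or shape
features are used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FeatureVector", "extract_features", "feature_matrix", "FEATURE_LENGTH"]

N_BINS = 256
FEATURE_LENGTH = N_BINS + 2


@dataclass(frozen=True)
class FeatureVector:
    """Normalized histogram (sums to 1), pixel mean, population variance."""

    histogram: np.ndarray
    mean: float
    variance: float

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.histogram, [self.mean, self.variance]])


def extract_features(img: np.ndarray) -> FeatureVector:
    """Compute the feature vector of one 8-bit grayscale image.

    Invariant to pixel permutation: only the intensity distribution matters.
    """
    img = np.asarray(img)
    if img.ndim != 2 or img.size == 0:
        raise ValueError(f"expected a non-empty 2-D image, got shape {img.shape}")
    flat = img.ravel().astype(np.int64)
    if flat.min() < 0 or flat.max() > 255:
        raise ValueError("gray image values must lie in [0, 255]")
    hist = np.bincount(flat, minlength=N_BINS).astype(np.float64)
    hist /= flat.size
    return FeatureVector(
        histogram=hist,
        mean=float(flat.mean()),
        variance=float(flat.var()),  # population variance (ddof=0)
    )


def feature_matrix(images: list[np.ndarray]) -> np.ndarray:
    """Stack feature vectors of many images into an (n, 258) matrix."""
    if not images:
        raise ValueError("need at least one image")
    return np.vstack([extract_features(im).as_array() for im in images])
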