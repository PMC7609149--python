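"""Thresholding, seeded region growing, and the end-to-end segmentation engine.

A predicted gray-level threshold binarizes the enhanced radiograph
(bright-hand convention: foreground = pixels >= t). Because markers, frame
fragments and noise also survive thresholding, the mask is cleaned by region
growing: flood-fill from the image-center seed keeps only the connected
component containing the hand and discards every disconnected false-positive
region. The cleaned mask then drives background removal, bounding-box
cropping and resizing of the final segmented image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .enhance import equalize_histogram
from .features import extract_features

__all__ = [
    "apply_threshold",
    "region_grow",
    "postprocess_crop",
    "segment_image",
    "SegmentationResult",
    "HandSegmenter",
]

_STRUCTURES = {
    8: np.ones((3, 3), dtype=bool),
    4: ndimage.generate_binary_structure(2, 1),
}


def apply_threshold(img: np.ndarray, t: int, polarity: str = "bright") -> np.ndarray:
    """Binarize at gray level ``t``: foreground = pixels >= t (bright hand);
    ``polarity='dark'`` inverts the comparison for inverted modalities."""
    if not 1 <= int(t) <= 255:
        raise ValueError(f"threshold must be in [1, 255], got {t}")
    img = np.asarray(img)
    if polarity == "bright":
        return img >= t
    if polarity == "dark":
        return img <= t
    raise ValueError(f"polarity must be 'bright' or 'dark', got {polarity!r}")


def _seed_pixel(mask: np.ndarray) -> tuple[int, int]:
    """Image center if foreground there, else the nearest foreground pixel
    (Euclidean; ties broken toward smaller row, then smaller column)."""
    rows, cols = mask.shape
    center = (rows // 2, cols // 2)
    if mask[center]:
        return center
    fg = np.argwhere(mask)
    d2 = (fg[:, 0] - center[0]) ** 2 + (fg[:, 1] - center[1]) ** 2
    order = np.lexsort((fg[:, 1], fg[:, 0], d2))  # distance, then row, then col
    r, c = fg[order[0]]
    return int(r), int(c)


def region_grow(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Keep only the connected foreground component containing the seed.

    The seed is the image center (with nearest-foreground fallback for
    off-center hands). Never adds pixels; an empty mask is returned as-is
    with a warning.
    """
    mask = np.asarray(mask).astype(bool)
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    if not mask.any():
        warnings.warn("region_grow received an empty mask", stacklevel=2)
        return mask.copy()
    labels, _ = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    return labels == labels[_seed_pixel(mask)]


def postprocess_crop(
    img: np.ndarray, mask: np.ndarray, out_size: tuple[int, int] = (512, 512)
) -> np.ndarray:
    """Zero the background, crop to the mask bounding box with a 5% margin,
    pad to square, and resize (bilinear) to ``out_size``."""
    img, mask = np.asarray(img), np.asarray(mask).astype(bool)
    if img.shape != mask.shape:
        raise ValueError(f"shape mismatch: {img.shape} vs {mask.shape}")
    if not mask.any():
        raise ValueError("cannot crop to an empty mask")
    fg = np.argwhere(mask)
    r0, c0 = fg.min(axis=0)
    r1, c1 = fg.max(axis=0)
    pad_r = int(round(0.05 * (r1 - r0 + 1)))
    pad_c = int(round(0.05 * (c1 - c0 + 1)))
    r0, c0 = max(r0 - pad_r, 0), max(c0 - pad_c, 0)
    r1, c1 = min(r1 + pad_r, img.shape[0] - 1), min(c1 + pad_c, img.shape[1] - 1)

    crop = (img * mask)[r0 : r1 + 1, c0 : c1 + 1].astype(np.float64)
    h, w = crop.shape
    side = max(h, w)
    square = np.zeros((side, side), dtype=np.float64)
    top, left = (side - h) // 2, (side - w) // 2
    square[top : top + h, left : left + w] = crop
    out = _sk_resize(square, out_size, order=1, preserve_range=True, anti_aliasing=False)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


@dataclass
class SegmentationResult:
    mask: np.ndarray  # cleaned boolean mask, original resolution
    segmented: np.ndarray | None  # cropped/resized uint8 image (None on failure)
    threshold: int
    status: str  # "ok" | "segmentation_failed"
    raw_mask: np.ndarray | None = None  # pre-cleanup mask, kept on failure


class HandSegmenter:
    """End-to-end engine: enhance -> features -> threshold prediction ->
    binarize -> region growing -> crop/resize.

    A light estimator wrapper around a :class:`ThresholdStackingClassifier`
    (or any classifier with fit/predict over gray-level labels): ``fit``
    derives per-image optimal-threshold labels from ground-truth masks,
    min-max normalizes the features, and trains the threshold predictor;
    ``predict`` segments new images.

    Parameters
    ----------
    stacker : classifier, optional
        Threshold predictor; defaults to the five-learner stacked ensemble.
    enhance : bool
        Apply histogram equalization before every stage (disable only for
        ablations on already-equalized data).
    polarity, connectivity, out_size
        Thresholding direction, region-growing connectivity, and the final
        segmented-image size.
    """

    def __init__(
        self,
        stacker=None,
        enhance: bool = True,
        polarity: str = "bright",
        connectivity: int = 8,
        out_size: tuple[int, int] = (512, 512),
        random_state: int | None = None,
    ):
        self.stacker = stacker
        self.enhance = enhance
        self.polarity = polarity
        self.connectivity = connectivity
        self.out_size = out_size
        self.random_state = random_state

    # -- sklearn-compatible param plumbing (images are lists, so we do not
    #    inherit the array-input validation machinery of BaseEstimator.fit)
    def get_params(self, deep: bool = True) -> dict:
        return {
            "stacker": self.stacker,
            "enhance": self.enhance,
            "polarity": self.polarity,
            "connectivity": self.connectivity,
            "out_size": self.out_size,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "HandSegmenter":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _enhanced(self, img: np.ndarray) -> np.ndarray:
        return equalize_histogram(img) if self.enhance else np.asarray(img)

    def fit(self, images: list[np.ndarray], masks: list[np.ndarray]) -> "HandSegmenter":
        from sklearn.base import clone

        from .labeling import MinMaxNormalizer, label_dataset
        from .stacker import ThresholdStackingClassifier

        if len(images) != len(masks):
            raise ValueError("images and masks must have equal length")
        enhanced = [self._enhanced(im) for im in images]
        labels_df = label_dataset(
            enhanced,
            masks,
            enhance=False,
            polarity=self.polarity,
            connectivity=self.connectivity,
        )
        ok = labels_df["status"].str.startswith("ok")
        if not ok.any():
            raise ValueError("no labelable training images")
        X = np.vstack(
            [extract_features(enhanced[i]).as_array() for i in np.flatnonzero(ok.values)]
        )
        y = labels_df.loc[ok, "label"].to_numpy(dtype=int)

        self.normalizer_ = MinMaxNormalizer().fit(X)
        base = (
            self.stacker
            if self.stacker is not None
            else ThresholdStackingClassifier(random_state=self.random_state)
        )
        self.stacker_ = clone(base).fit(self.normalizer_.transform(X), y)
        self.labels_ = labels_df
        return self

    @classmethod
    def from_fitted(cls, stacker, normalizer, **params) -> "HandSegmenter":
        """Assemble an engine from an already-trained predictor and its
        feature normalizer (the CLI's staged workflow)."""
        self = cls(**params)
        self.stacker_ = stacker
        self.normalizer_ = normalizer
        return self

    def predict_threshold(self, image: np.ndarray) -> int:
        self._check_fitted()
        fv = extract_features(self._enhanced(image)).as_array()
        x = self.normalizer_.transform(fv[None, :])
        return int(self.stacker_.predict(x)[0])

    def segment(self, image: np.ndarray) -> SegmentationResult:
        self._check_fitted()
        enhanced = self._enhanced(image)
        t = self.predict_threshold(image)
        raw = apply_threshold(enhanced, t, polarity=self.polarity)
        if not raw.any():
            return SegmentationResult(
                mask=raw, segmented=None, threshold=t, status="segmentation_failed",
                raw_mask=raw,
            )
        cleaned = region_grow(raw, connectivity=self.connectivity)
        segmented = postprocess_crop(enhanced, cleaned, out_size=self.out_size)
        return SegmentationResult(mask=cleaned, segmented=segmented, threshold=t, status="ok")

    def predict(self, images: list[np.ndarray]) -> list[SegmentationResult]:
        return [self.segment(im) for im in images]

    def _check_fitted(self) -> None:
        if not hasattr(self, "stacker_") or not hasattr(self, "normalizer_"):
            raise ValueError("HandSegmenter is not fitted yet; call fit first")


def segment_image(img_raw: np.ndarray, model: HandSegmenter) -> tuple[np.ndarray, np.ndarray | None, int]:
    """Functional form of :meth:`HandSegmenter.segment`: returns the cleaned
    mask (original resolution), the final cropped image, and the threshold."""
    res = model.segment(img_raw)
    return res.mask, res.segmented, res.threshold
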