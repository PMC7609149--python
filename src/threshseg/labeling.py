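"""Supervised target construction: the optimal binarization threshold.

Casting segmentation as classification needs a label per image — the gray
level that best separates hand from background. The search grid is 40
candidate values spaced 2 apart *below* the image mean (of the enhanced
image); if none is acceptable the grid is extended a limited amount above
the mean. Candidate quality is scored as the Dice coefficient between the
region-grown thresholded mask and the ground truth, an automated surrogate
for the manual judgment "background completely separated, mask details
exquisite"; ties favor the larger threshold, which keeps fine structure
(thin finger edges) from bleeding into the background.

Labels remain integer gray levels; only feature columns pass through the
dataset-level min-max normalization, whose (min, max) are frozen at training
time and reused verbatim on test features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enhance import equalize_histogram
from .metrics import dsc
from .segment import apply_threshold, region_grow

__all__ = [
    "candidate_thresholds",
    "extend_candidates",
    "score_threshold",
    "select_optimal_threshold",
    "LabelResult",
    "label_dataset",
    "MinMaxNormalizer",
]

N_CANDIDATES = 40
GRID_STEP = 2
DSC_FLOOR = 0.5  # below this no candidate is "acceptable"
N_EXTRA_DEFAULT = 10
_TIE_TOL = 1e-12


def candidate_thresholds(img: np.ndarray) -> list[int]:
    """The base grid: floor(mean) - 2k for k = 1..40, clipped at >= 1,
    descending. Exactly 40 values whenever floor(mean) >= 81."""
    base = int(np.floor(np.asarray(img).mean()))
    return [base - GRID_STEP * k for k in range(1, N_CANDIDATES + 1) if base - GRID_STEP * k >= 1]


def extend_candidates(img: np.ndarray, n_extra: int = N_EXTRA_DEFAULT) -> list[int]:
    """Extension grid above the mean: floor(mean) + 2j, j = 1..n_extra,
    capped at 255 (duplicate caps dropped)."""
    base = int(np.floor(np.asarray(img).mean()))
    out: list[int] = []
    for j in range(1, n_extra + 1):
        t = min(base + GRID_STEP * j, 255)
        if not out or t != out[-1]:
            out.append(t)
    return out


def score_threshold(
    img: np.ndarray,
    t: int,
    gt: np.ndarray,
    polarity: str = "bright",
    connectivity: int = 8,
) -> float:
    """Dice score of the *cleaned* (region-grown) threshold mask against the
    ground truth; the quality the label search maximizes."""
    img, gt = np.asarray(img), np.asarray(gt).astype(bool)
    if img.shape != gt.shape:
        raise ValueError(f"shape mismatch: {img.shape} vs {gt.shape}")
    mask = apply_threshold(img, t, polarity=polarity)
    if mask.any():
        mask = region_grow(mask, connectivity=connectivity)
    return dsc(mask, gt)


@dataclass(frozen=True)
class LabelResult:
    threshold: int | None
    best_dsc: float
    status: str  # "ok" | "ok_extended" | "unlabelable"


def _argmax_larger_t(cands: list[int], scores: list[float]) -> tuple[int, float]:
    best = max(scores)
    winners = [t for t, s in zip(cands, scores) if s >= best - _TIE_TOL]
    return max(winners), best


def select_optimal_threshold(
    img: np.ndarray,
    gt: np.ndarray,
    polarity: str = "bright",
    connectivity: int = 8,
    dsc_floor: float = DSC_FLOOR,
) -> LabelResult:
    """Best candidate by Dice score, ties toward the larger threshold.

    If the whole base grid scores below ``dsc_floor`` the extension grid is
    searched once; an image that still has no acceptable candidate is
    reported as ``unlabelable`` rather than raising.
    """
    cands = candidate_thresholds(img)
    scores = [score_threshold(img, t, gt, polarity, connectivity) for t in cands]
    if cands:
        t, best = _argmax_larger_t(cands, scores)
        if best >= dsc_floor:
            return LabelResult(t, best, "ok")
    extra = extend_candidates(img)
    if extra:
        ex_scores = [score_threshold(img, t, gt, polarity, connectivity) for t in extra]
        all_c = cands + extra
        all_s = scores + ex_scores
        t, best = _argmax_larger_t(all_c, all_s)
        if best >= dsc_floor:
            return LabelResult(t, best, "ok_extended")
        return LabelResult(None, best, "unlabelable")
    return LabelResult(None, max(scores, default=0.0), "unlabelable")


def label_dataset(
    images: list[np.ndarray],
    masks: list[np.ndarray],
    names: list[str] | None = None,
    enhance: bool = True,
    polarity: str = "bright",
    connectivity: int = 8,
) -> pd.DataFrame:
    """Label a whole image set; columns: name, label, best_dsc, status."""
    if len(images) != len(masks):
        raise ValueError("images and masks must have equal length")
    if names is None:
        names = [f"img_{i:04d}" for i in range(len(images))]
    rows = []
    for name, img, gt in zip(names, images, masks):
        work = equalize_histogram(img) if enhance else img
        res = select_optimal_threshold(work, gt, polarity, connectivity)
        rows.append(
            {"name": name, "label": res.threshold, "best_dsc": res.best_dsc, "status": res.status}
        )
    return pd.DataFrame(rows)


class MinMaxNormalizer:
    """Columnwise min-max normalization with frozen training-set bounds.

    x -> (x - min) / (max - min) per feature column; the (min, max) pairs are
    learned once on the training matrix and reapplied unchanged to test
    features, so test values may legitimately fall slightly outside [0, 1].
    A constant column carries no information and is mapped to 0.5 (with a
    warning) instead of dividing by zero.
    """

    def fit(self, X: np.ndarray) -> "MinMaxNormalizer":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("expected a non-empty 2-D feature matrix")
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        self.constant_cols_ = self.data_max_ == self.data_min_
        if self.constant_cols_.any():
            warnings.warn(
                f"{int(self.constant_cols_.sum())} constant feature column(s) mapped to 0.5",
                stacklevel=2,
            )
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "data_min_"):
            raise ValueError("MinMaxNormalizer is not fitted yet")
        X = np.asarray(X, dtype=np.float64)
        span = np.where(self.constant_cols_, 1.0, self.data_max_ - self.data_min_)
        out = (X - self.data_min_) / span
        out[:, self.constant_cols_] = 0.5
        return out

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    # minimal sklearn param plumbing (stateless constructor)
    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "MinMaxNormalizer":
        if params:
            raise ValueError(f"unknown parameters {sorted(params)}")
        return self
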