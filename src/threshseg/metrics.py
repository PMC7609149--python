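"""Segmentation evaluation metrics: MSE/PSNR, global SSIM, DSC, JSI.

PSNR and SSIM grade image fidelity; DSC (Dice similarity coefficient) and
JSI (Jaccard similarity index) grade mask overlap. SSIM here is the single
global statistic

    SSIM = (2 mu_S mu_G + C1)(2 sigma_SG + C2)
           / ((mu_S^2 + mu_G^2 + C1)(sigma_S^2 + sigma_G^2 + C2))

computed over whole images — deliberately *not* the sliding-window mean-SSIM
variant. DSC and JSI are linked by the identity JSI = DSC / (2 - DSC).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.transform import resize

__all__ = ["mse", "psnr", "ssim", "dsc", "jsi", "evaluate_set"]

#: default SSIM stabilizers, the standard K1=0.01 / K2=0.03 convention at L=255
C1_DEFAULT = (0.01 * 255) ** 2
C2_DEFAULT = (0.03 * 255) ** 2


def _as_pair(s, g, binary: bool = False) -> tuple[np.ndarray, np.ndarray]:
    s, g = np.asarray(s), np.asarray(g)
    if s.shape != g.shape:
        raise ValueError(f"shape mismatch: {s.shape} vs {g.shape}")
    if binary:
        for name, a in (("S", s), ("G", g)):
            if a.dtype != bool and not np.isin(np.unique(a), (0, 1)).all():
                raise ValueError(f"{name} must be binary (bool or 0/1)")
        return s.astype(bool), g.astype(bool)
    return s.astype(np.float64), g.astype(np.float64)


def mse(s: np.ndarray, g: np.ndarray, resize_to_256: bool = False) -> float:
    """Mean squared error. With ``resize_to_256`` both inputs are first
    resampled to 256x256 so the normalization is the fixed 1/(256*256)."""
    s, g = _as_pair(s, g)
    if resize_to_256:
        s = resize(s, (256, 256), order=1, preserve_range=True, anti_aliasing=False)
        g = resize(g, (256, 256), order=1, preserve_range=True, anti_aliasing=False)
    return float(np.mean((s - g) ** 2))


def psnr(s: np.ndarray, g: np.ndarray, resize_to_256: bool = False) -> float:
    """Peak signal-to-noise ratio, 10*log10(255^2 / MSE) dB; identical
    images return +inf (excluded from means downstream, never capped)."""
    m = mse(s, g, resize_to_256=resize_to_256)
    if m == 0.0:
        return float("inf")
    return float(10.0 * np.log10(255.0**2 / m))


def ssim(
    s: np.ndarray, g: np.ndarray, c1: float = C1_DEFAULT, c2: float = C2_DEFAULT
) -> float:
    """Global (non-windowed) structural similarity of two images."""
    if c1 <= 0 or c2 <= 0:
        raise ValueError("SSIM stabilizers C1, C2 must be > 0")
    s, g = _as_pair(s, g)
    mu_s, mu_g = s.mean(), g.mean()
    var_s, var_g = s.var(), g.var()
    cov = ((s - mu_s) * (g - mu_g)).mean()
    return float(
        (2 * mu_s * mu_g + c1)
        * (2 * cov + c2)
        / ((mu_s**2 + mu_g**2 + c1) * (var_s + var_g + c2))
    )


def dsc(s: np.ndarray, g: np.ndarray) -> float:
    """Dice similarity coefficient 2|S∩G| / (|S|+|G|); two empty masks agree
    perfectly and score 1."""
    s, g = _as_pair(s, g, binary=True)
    denom = s.sum() + g.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(s, g).sum() / denom)


def jsi(s: np.ndarray, g: np.ndarray) -> float:
    """Jaccard similarity index |S∩G| / |S∪G|; empty/empty scores 1."""
    s, g = _as_pair(s, g, binary=True)
    union = np.logical_or(s, g).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(s, g).sum() / union)


def evaluate_set(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    names: list[str] | None = None,
    resize_to_256: bool = False,
) -> pd.DataFrame:
    """Per-image and mean metrics for (segmented, ground-truth) pairs.

    Boolean masks are scaled to {0, 255} for PSNR/SSIM so the intensity
    metrics see 8-bit dynamics; DSC/JSI use the binary form. The returned
    frame has one row per image plus a ``mean`` row in which infinite PSNR
    values are excluded (column ``n_inf_psnr`` counts them).
    """
    if not pairs:
        raise ValueError("need at least one pair")
    if names is None:
        names = [f"img_{i:04d}" for i in range(len(pairs))]
    rows = []
    for name, (s, g) in zip(names, pairs):
        s, g = np.asarray(s), np.asarray(g)
        s_img = s.astype(np.uint8) * 255 if s.dtype == bool else s
        g_img = g.astype(np.uint8) * 255 if g.dtype == bool else g
        rows.append(
            {
                "name": name,
                "psnr": psnr(s_img, g_img, resize_to_256=resize_to_256),
                "ssim": ssim(s_img, g_img),
                "dsc": dsc(s != 0, g != 0),
                "jsi": jsi(s != 0, g != 0),
            }
        )
    df = pd.DataFrame(rows)
    finite = df["psnr"][np.isfinite(df["psnr"])]
    mean_row = {
        "name": "mean",
        "psnr": float(finite.mean()) if len(finite) else float("inf"),
        "ssim": float(df["ssim"].mean()),
        "dsc": float(df["dsc"].mean()),
        "jsi": float(df["jsi"].mean()),
        "n_inf_psnr": int((~np.isfinite(df["psnr"])).sum()),
    }
    df["n_inf_psnr"] = 0
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
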