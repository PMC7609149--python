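"""Synthetic radiograph phantoms with known ground-truth hand masks.

Generates 8-bit grayscale images that mimic the intensity structure of a
pediatric hand radiograph: a bright, connected, hand-like foreground on a
dark background, a bimodal intensity histogram with controllable mode
overlap, an uneven-illumination ramp, additive Gaussian noise, and small
bright distractor blobs (radioactive markers, frame fragments) placed
*outside* the hand so that only connectivity-based cleanup — not
thresholding — can remove them.

The hand shape is a parametric blob (elliptical palm plus five elliptical
finger lobes), not an anatomical model: the downstream pipeline consumes
only intensity statistics and connectivity, so shape realism buys nothing.

All randomness flows from one user-supplied seed through a counter-based
per-sample stream (`numpy.random.SeedSequence(seed, spawn_key=(i,))`), so a
dataset is reproducible sample-by-sample, not just as a whole.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse

__all__ = [
    "PhantomParams",
    "JitterSpec",
    "PhantomSample",
    "generate_phantom",
    "generate_dataset",
]

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


@dataclass(frozen=True)
class PhantomParams:
    """Generation parameters for one phantom radiograph.

    Intensities are gray levels in [0, 255]. ``illumination_gradient`` is the
    peak-to-peak amplitude of an additive linear ramp in a random direction;
    ``noise_std`` is pixelwise additive Gaussian noise applied last.
    """

    image_size: tuple[int, int] = (128, 128)
    fg_mean: float = 180.0
    fg_std: float = 12.0
    bg_mean: float = 70.0
    bg_std: float = 10.0
    illumination_gradient: float = 15.0
    n_artifacts: int = 3
    noise_std: float = 4.0
    seed: int = 0
    # internal shape controls (relative to image size); jitter may scale them
    palm_scale: float = 1.0
    finger_scale: float = 1.0

    def validate(self) -> None:
        rows, cols = self.image_size
        if rows < 32 or cols < 32:
            raise ValueError(f"image_size must be at least (32, 32), got {self.image_size}")
        if not (0 <= self.bg_mean < self.fg_mean <= 255):
            raise ValueError(
                f"need 0 <= bg_mean < fg_mean <= 255, got bg={self.bg_mean}, fg={self.fg_mean}"
            )
        for name in ("fg_std", "bg_std", "noise_std", "illumination_gradient"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_artifacts < 0:
            raise ValueError("n_artifacts must be >= 0")
        if not (0.5 <= self.palm_scale <= 1.5 and 0.5 <= self.finger_scale <= 1.5):
            raise ValueError("palm_scale and finger_scale must lie in [0.5, 1.5]")


@dataclass(frozen=True)
class JitterSpec:
    """Per-sample parameter jitter for :func:`generate_dataset`.

    Each range is a uniform additive offset (means) or multiplicative factor
    (shape scales) drawn independently per sample, so the optimal threshold
    varies across the dataset the way it does across real radiographs.
    """

    fg_mean_range: tuple[float, float] = (-20.0, 20.0)
    bg_mean_range: tuple[float, float] = (-15.0, 15.0)
    palm_scale_range: tuple[float, float] = (0.92, 1.08)
    finger_scale_range: tuple[float, float] = (0.9, 1.1)

    @classmethod
    def none(cls) -> "JitterSpec":
        """Zero jitter: every sample identical up to its noise stream."""
        return cls((0.0, 0.0), (0.0, 0.0), (1.0, 1.0), (1.0, 1.0))


@dataclass(frozen=True)
class PhantomSample:
    image: np.ndarray  # uint8, (rows, cols)
    mask: np.ndarray  # bool, (rows, cols); True = hand
    params: PhantomParams
    artifact_mask: np.ndarray | None = None  # bool; True = distractor blob pixels


def _hand_mask(params: PhantomParams) -> np.ndarray:
    """Draw the hand blob: elliptical palm, forearm entering from the bottom
    edge, and five elliptical finger lobes fanned above the palm. Single
    8-connected component containing the image center; covers roughly half
    the frame, as a collimated pediatric hand view does."""
    rows, cols = params.image_size
    mask = np.zeros((rows, cols), dtype=bool)
    r0, c0 = rows / 2.0, cols / 2.0

    palm_r = 0.34 * rows * params.palm_scale
    palm_c = 0.30 * cols * params.palm_scale
    palm_center = (r0 + 0.04 * rows, c0)
    rr, cc = ellipse(palm_center[0], palm_center[1], palm_r, palm_c, shape=mask.shape)
    mask[rr, cc] = True

    # forearm: vertical band from the palm to the bottom edge
    half_w = 0.23 * cols * params.palm_scale
    wrist_top = int(palm_center[0])
    c_lo = max(int(palm_center[1] - half_w), 0)
    c_hi = min(int(palm_center[1] + half_w) + 1, cols)
    mask[wrist_top:rows, c_lo:c_hi] = True

    # five finger lobes fanned above the palm; middle finger longest
    angles = np.deg2rad([-52.0, -26.0, 0.0, 26.0, 52.0])
    lengths = np.array([0.21, 0.27, 0.31, 0.27, 0.22]) * rows * params.finger_scale
    width = max(0.065 * cols * params.finger_scale, 1.5)
    for ang, length in zip(angles, lengths):
        # finger center sits so the lobe overlaps the palm boundary by ~30%
        dist = palm_r + 0.5 * length - 0.3 * length
        fr = palm_center[0] - dist * math.cos(ang)
        fc = palm_center[1] + dist * math.sin(ang)
        rr, cc = ellipse(fr, fc, 0.5 * length, width, rotation=-ang, shape=mask.shape)
        mask[rr, cc] = True

    return mask


def _place_artifacts(
    mask: np.ndarray, n: int, rng: np.random.Generator
) -> list[tuple[int, int, int]]:
    """Random small discs (row, col, radius) strictly disjoint from the hand,
    with a >=2-pixel gap so 8-connected growth can never bridge to them."""
    rows, cols = mask.shape
    forbidden = ndimage.binary_dilation(mask, structure=_EIGHT, iterations=3)
    placed: list[tuple[int, int, int]] = []
    attempts = 0
    while len(placed) < n and attempts < 200 * max(n, 1):
        attempts += 1
        radius = int(rng.integers(2, 5))
        r = int(rng.integers(radius, rows - radius))
        c = int(rng.integers(radius, cols - radius))
        rr, cc = ellipse(r, c, radius, radius, shape=mask.shape)
        if forbidden[rr, cc].any():
            continue
        placed.append((r, c, radius))
        forbidden[rr, cc] = True
    return placed


def generate_phantom(params: PhantomParams) -> PhantomSample:
    """Generate one phantom; bit-identical for identical ``params``."""
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    rows, cols = params.image_size

    mask = _hand_mask(params)

    img = rng.normal(params.bg_mean, params.bg_std, size=(rows, cols))
    fg = rng.normal(params.fg_mean, params.fg_std, size=(rows, cols))
    img[mask] = fg[mask]

    # bright distractors: a bit above the foreground mode, outside the hand
    artifact_level = min(params.fg_mean + 25.0, 255.0)
    artifact_mask = np.zeros_like(mask)
    for r, c, radius in _place_artifacts(mask, params.n_artifacts, rng):
        rr, cc = ellipse(r, c, radius, radius, shape=mask.shape)
        img[rr, cc] = artifact_level + rng.normal(0.0, params.fg_std, size=rr.size)
        artifact_mask[rr, cc] = True

    if params.illumination_gradient > 0:
        theta = rng.uniform(0.0, 2.0 * math.pi)
        rgrid, cgrid = np.meshgrid(
            np.linspace(0.0, 1.0, rows), np.linspace(0.0, 1.0, cols), indexing="ij"
        )
        ramp = math.cos(theta) * rgrid + math.sin(theta) * cgrid
        ramp -= ramp.min()
        if ramp.max() > 0:
            ramp /= ramp.max()
        img += params.illumination_gradient * ramp

    if params.noise_std > 0:
        img += rng.normal(0.0, params.noise_std, size=(rows, cols))

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return PhantomSample(image=img, mask=mask, params=params, artifact_mask=artifact_mask)


def generate_dataset(
    n: int,
    params: PhantomParams | None = None,
    jitter: JitterSpec | None = None,
) -> list[PhantomSample]:
    """Generate ``n`` phantoms with per-sample parameter jitter.

    ``params.seed`` is the master seed; sample *i* draws from the
    counter-based stream ``SeedSequence(master, spawn_key=(i,))`` so the set
    is reproducible and order-independent of generation batching.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    params = params if params is not None else PhantomParams()
    params.validate()
    jitter = jitter if jitter is not None else JitterSpec()

    samples = []
    for i in range(n):
        ss = np.random.SeedSequence(params.seed, spawn_key=(i,))
        jit_rng = np.random.default_rng(ss)
        # sample 0 keeps the master seed so a zero-jitter singleton dataset
        # coincides with generate_phantom(params)
        sample_seed = params.seed if i == 0 else int(jit_rng.integers(0, 2**31 - 1))
        fg = params.fg_mean + jit_rng.uniform(*jitter.fg_mean_range)
        bg = params.bg_mean + jit_rng.uniform(*jitter.bg_mean_range)
        fg = float(np.clip(fg, 1.0, 255.0))
        bg = float(np.clip(bg, 0.0, fg - 1.0))
        p_i = replace(
            params,
            seed=sample_seed,
            fg_mean=fg,
            bg_mean=bg,
            palm_scale=float(jit_rng.uniform(*jitter.palm_scale_range)),
            finger_scale=float(jit_rng.uniform(*jitter.finger_scale_range)),
        )
        samples.append(generate_phantom(p_i))
    return samples
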