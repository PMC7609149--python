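"""Image and model I/O: 8-bit PNG/TIFF, optional DICOM, joblib model files."""

from __future__ import annotations

from pathlib import Path

import joblib
import numpy as np
from PIL import Image

__all__ = ["read_image", "write_image", "write_mask", "read_mask", "save_model", "load_model"]

MODEL_FORMAT_VERSION = 1

_DICOM_SUFFIXES = {".dcm", ".dicom"}


def _dicom_to_uint8(path: Path) -> np.ndarray:
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(np.float64)
    # window/level when present, else min-max
    wc, ww = getattr(ds, "WindowCenter", None), getattr(ds, "WindowWidth", None)
    if wc is not None and ww is not None:
        wc = float(wc[0] if isinstance(wc, pydicom.multival.MultiValue) else wc)
        ww = float(ww[0] if isinstance(ww, pydicom.multival.MultiValue) else ww)
        lo, hi = wc - ww / 2.0, wc + ww / 2.0
    else:
        lo, hi = arr.min(), arr.max()
    if hi <= lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    arr = np.clip((arr - lo) / (hi - lo), 0.0, 1.0)
    return np.rint(arr * 255).astype(np.uint8)


def read_image(path: str | Path) -> np.ndarray:
    """Read an image as 2-D uint8. RGB inputs are converted by luminance;
    16-bit grayscale is min-max mapped to [0, 255]; DICOM is window/level
    mapped when window tags exist, min-max otherwise."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    if path.suffix.lower() in _DICOM_SUFFIXES:
        return _dicom_to_uint8(path)
    try:
        with Image.open(path) as im:
            if im.mode in ("I", "I;16", "I;16B", "F"):
                arr = np.asarray(im, dtype=np.float64)
                lo, hi = arr.min(), arr.max()
                if hi <= lo:
                    return np.zeros(arr.shape, dtype=np.uint8)
                return np.rint((arr - lo) / (hi - lo) * 255).astype(np.uint8)
            return np.asarray(im.convert("L"), dtype=np.uint8)
    except Exception as exc:  # pragma: no cover - PIL error surface varies
        raise IOError(f"cannot read image {path}: {exc}") from exc


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write a 2-D uint8 image losslessly (PNG/TIFF by extension)."""
    img = np.asarray(img)
    if img.dtype == bool:
        write_mask(img, path)
        return
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    Image.fromarray(img.astype(np.uint8), mode="L").save(str(path))


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as {0, 255} 8-bit PNG/TIFF."""
    mask = np.asarray(mask).astype(bool)
    Image.fromarray(mask.astype(np.uint8) * 255, mode="L").save(str(path))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a {0, 255} mask image back to boolean (any nonzero = True)."""
    return read_image(path) > 127


def save_model(model, path: str | Path) -> None:
    """Serialize a trained engine or stacker with a format-version header."""
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, str(path))


def load_model(path: str | Path):
    payload = joblib.load(str(path))
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise IOError(f"{path} is not a threshseg model file")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise IOError(
            f"unsupported model format version {payload['format_version']}"
        )
    return payload["model"]
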