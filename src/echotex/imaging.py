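"""Image loading, 8-bit grayscale conversion, ROI extraction and echo intensity.

Echo intensity (EI) is the first-order mean gray level of an ultrasound
region of interest on the 0 (black) – 255 (white) scale; it is the
conventional echogenicity readout, but depends on scanner gain/settings.
All second-order texture statistics consume the same fixed-size ROI
(:class:`RoiSpec`, default 50 x 50 pixels).

Conventions: images are 2-D ``uint8`` numpy arrays, row-major, 0-based
indices, ROI windows half-open ``[row0, row0+side) x [col0, col0+side)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image


class FormatError(ValueError):
    """Unreadable file, wrong channel count, or unsupported bit depth."""


class BoundsError(ValueError):
    """ROI not fully inside the image, or empty ROI."""


@dataclass(frozen=True)
class RoiSpec:
    """Axis-aligned square region of interest.

    Parameters
    ----------
    row0, col0 : int
        0-based top-left pixel of the window.
    side : int
        Window edge length in pixels (default 50, the fixed ROI size
        used for muscle texture analysis).
    """

    row0: int
    col0: int
    side: int = 50

    def __post_init__(self) -> None:
        if self.side < 2:
            raise BoundsError(f"ROI side must be >= 2, got {self.side}")
        if self.row0 < 0 or self.col0 < 0:
            raise BoundsError("ROI origin must be non-negative")


def to_gray8(rgb: np.ndarray, *, weights: str = "mean") -> np.ndarray:
    """Convert an RGB array (H, W, 3) to 8-bit grayscale.

    Default is the unweighted channel mean with round-half-to-even
    (the ImageJ-style "RGB to 8-bit" conversion without luminance
    weighting). ``weights="luminance"`` selects Rec. 601 weights
    (0.299, 0.587, 0.114) instead.
    """
    arr = np.asarray(rgb)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"expected (H, W, 3) RGB array, got shape {arr.shape}")
    if weights == "mean":
        g = arr.astype(np.float64).mean(axis=2)
    elif weights == "luminance":
        g = arr.astype(np.float64) @ np.array([0.299, 0.587, 0.114])
    else:
        raise ValueError(f"unknown conversion weights {weights!r}")
    return np.clip(np.round(g), 0, 255).astype(np.uint8)


def load_image(path: str | Path, *, weights: str = "mean",
               rescale_16bit: bool = False) -> np.ndarray:
    """Load a PNG/TIFF still as an 8-bit grayscale array.

    RGB(A) inputs are converted via :func:`to_gray8`; 16-bit inputs are
    rejected unless ``rescale_16bit`` is set, in which case they are
    linearly rescaled by 1/257 (65535 -> 255). Rejecting by default avoids
    silently redefining the gray-level scale that EI is reported on.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            if mode in ("L", "P"):
                return np.asarray(im.convert("L"), dtype=np.uint8)
            if mode in ("RGB", "RGBA"):
                return to_gray8(np.asarray(im.convert("RGB")), weights=weights)
            if mode in ("I", "I;16", "I;16B", "I;16L"):
                if not rescale_16bit:
                    raise FormatError(
                        f"{path.name}: 16-bit input; pass rescale_16bit=True "
                        "to map 0-65535 onto 0-255 explicitly")
                arr = np.asarray(im, dtype=np.float64)
                return np.clip(np.round(arr / 257.0), 0, 255).astype(np.uint8)
            raise FormatError(f"{path.name}: unsupported image mode {mode!r}")
    except FormatError:
        raise
    except Exception as exc:  # unreadable / truncated / not an image
        raise FormatError(f"cannot read image {path}: {exc}") from exc


def save_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write an 8-bit grayscale array as PNG or TIFF (by extension)."""
    arr = np.asarray(pixels)
    if arr.dtype != np.uint8:
        if arr.min() < 0 or arr.max() > 255:
            raise FormatError("pixel values outside [0, 255]")
        arr = arr.astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def extract_roi(image: np.ndarray, spec: RoiSpec) -> np.ndarray:
    """Copy the square window addressed by ``spec`` out of ``image``.

    Raises :class:`BoundsError` if the window is not fully inside the
    image; there is no silent clamping.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise FormatError(f"expected 2-D grayscale image, got shape {img.shape}")
    h, w = img.shape
    if spec.row0 + spec.side > h or spec.col0 + spec.side > w:
        raise BoundsError(
            f"ROI [{spec.row0}:{spec.row0 + spec.side}, "
            f"{spec.col0}:{spec.col0 + spec.side}] exceeds image {h}x{w}")
    return img[spec.row0:spec.row0 + spec.side,
               spec.col0:spec.col0 + spec.side].copy()


def echo_intensity(roi: np.ndarray) -> float:
    """Mean gray level of the ROI (first-order echo intensity, 0-255 AU)."""
    arr = np.asarray(roi)
    if arr.size == 0:
        raise BoundsError("empty ROI")
    return float(arr.astype(np.float64).mean())
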