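"""Reading and writing grayscale images and binary vessel masks.

Images are plain 2-D float arrays with intensities in [0, 1]; masks are 2-D
boolean arrays. PNG/JPEG input is converted to grayscale via luminance.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .errors import StenokitError

MIN_SIDE = 32


def validate_gray_image(pixels: np.ndarray) -> np.ndarray:
    """Check the grayscale-image contract: 2-D, finite, in [0,1], >= 32x32."""
    arr = np.asarray(pixels, dtype=float)
    if arr.ndim != 2:
        raise StenokitError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    if arr.shape[0] < MIN_SIDE or arr.shape[1] < MIN_SIDE:
        raise StenokitError(f"image too small: {arr.shape}, need >= {MIN_SIDE}x{MIN_SIDE}")
    if not np.all(np.isfinite(arr)):
        raise StenokitError("image contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise StenokitError("image intensities must lie in [0, 1]")
    return arr


def load_gray_image(path: str | Path) -> np.ndarray:
    """Load a PNG/JPEG as a [0,1] grayscale array (luminance conversion)."""
    with Image.open(path) as im:
        gray = im.convert("L")
        arr = np.asarray(gray, dtype=float) / 255.0
    return validate_gray_image(arr)


def save_gray_image(path: str | Path, pixels: np.ndarray) -> None:
    arr = np.clip(np.asarray(pixels, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8)).save(path)


def load_mask(path: str | Path) -> np.ndarray:
    """Load a binary mask stored as an 8-bit PNG (foreground = any value > 127)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr > 127


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as 0/255 8-bit PNG."""
    mask = np.asarray(mask, dtype=bool)
    Image.fromarray(np.where(mask, 255, 0).astype(np.uint8)).save(path)
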