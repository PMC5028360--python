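"""Raster containers and validation helpers.

The package follows the scikit-image convention of operating on bare
numpy arrays:

* an RGB image is an ``(H, W, 3)`` ``uint8`` array, channel order R, G, B;
* a binary mask is an ``(H, W)`` boolean array, ``True`` = foreground;
* a gray image is a :class:`GrayImage` — a float raster bundled with the
  value range it is declared over, so thresholding stages can quantize
  real-valued channels (e.g. CIELAB ``a``/``b``) consistently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GrayImage",
    "as_rgb",
    "as_mask",
    "ContractError",
]


class ContractError(ValueError):
    """An input violated a documented precondition."""


def as_rgb(img: np.ndarray) -> np.ndarray:
    """Validate and return an 8-bit RGB image array."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ContractError(f"expected (H, W, 3) RGB array, got shape {img.shape}")
    if img.shape[0] < 8 or img.shape[1] < 8:
        raise ContractError(f"image too small: {img.shape[:2]} (need >= 8x8)")
    if img.dtype != np.uint8:
        if np.nanmin(img) < 0 or np.nanmax(img) > 255:
            raise ContractError("RGB values must lie in [0, 255]")
        img = img.astype(np.uint8)
    return img


def as_mask(mask: np.ndarray, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Validate and return a boolean mask, optionally checking its shape."""
    mask = np.asarray(mask)
    if mask.dtype != bool:
        if not np.isin(mask, (0, 1)).all():
            raise ContractError("mask values must be boolean or 0/1")
        mask = mask.astype(bool)
    if mask.ndim != 2:
        raise ContractError(f"expected 2-D mask, got shape {mask.shape}")
    if shape is not None and mask.shape != tuple(shape):
        raise ContractError(f"mask shape {mask.shape} != expected {tuple(shape)}")
    return mask


@dataclass(frozen=True)
class GrayImage:
    """A single-channel raster with a declared value range.

    Parameters
    ----------
    pixels : ndarray of float, shape (H, W)
    value_range : (lo, hi)
        The range the pixel values are declared over; thresholding
        quantizes 256 uniform bins across this range.
    """

    pixels: np.ndarray
    value_range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ContractError(f"expected 2-D gray image, got shape {px.shape}")
        if not np.isfinite(px).all():
            raise ContractError("gray image contains non-finite values")
        lo, hi = self.value_range
        if not lo < hi:
            raise ContractError(f"invalid value range {self.value_range}")
        if px.size and (px.min() < lo - 1e-9 or px.max() > hi + 1e-9):
            raise ContractError(
                f"pixel values [{px.min():.4g}, {px.max():.4g}] exceed "
                f"declared range {self.value_range}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "GrayImage":
        """Same declared range, new pixel data (clipped to range)."""
        lo, hi = self.value_range
        return GrayImage(np.clip(pixels, lo, hi), self.value_range)
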