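"""Morphological cleanup of the raw wavelet mask.

The raw mask usually carries holes (intensity variation inside the
lesion), satellite islands (hair residue, bubbles, skin texture) and a
blocky, ragged boundary from the quarter-resolution upsampling.  The
final lesion mask is produced by: subtracting the dark-corner mask,
filling enclosed holes, keeping the dominant component plus any island
close enough to merge into it, opening, and smoothing the boundary by a
circular moving average over the traced boundary coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import polygon
from skimage.measure import find_contours
from skimage.morphology import closing, dilation, erosion, disk

from .images import ContractError, as_mask

__all__ = [
    "MorphologyConfig",
    "fill_holes",
    "manage_islands",
    "smooth_boundary",
    "postprocess",
]


@dataclass(frozen=True)
class MorphologyConfig:
    """Tunables of the cleanup stage.

    ``merge_distance`` (px) is how near an island must be to the main
    component to be kept and bridged; ``smooth_window`` is the moving-
    average window (odd, in boundary samples) for boundary smoothing.
    """

    fill_holes: bool = True
    min_island_area: int = 100
    merge_distance: int = 20
    erosion_radius: int = 3
    dilation_radius: int = 3
    smooth_window: int = 15

    def validate(self) -> None:
        if self.min_island_area < 0 or self.merge_distance < 0:
            raise ContractError("areas and distances must be >= 0")
        if self.erosion_radius < 0 or self.dilation_radius < 0:
            raise ContractError("radii must be >= 0")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ContractError(f"smooth_window must be odd >= 1, got {self.smooth_window}")


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Set background regions not 4-connected to the border to foreground."""
    mask = as_mask(mask)
    return ndimage.binary_fill_holes(mask)  # default structure = 4-connectivity


def manage_islands(mask: np.ndarray, cfg: MorphologyConfig | None = None) -> np.ndarray:
    """Keep the dominant component, merge near islands, drop far ones.

    Components whose minimal distance to the largest component is within
    ``cfg.merge_distance`` are kept and bridged by morphological closing;
    everything else is removed.  A single opening (erosion + dilation
    with the configured radii) finishes the step.  An empty mask is
    returned empty with a warning.
    """
    mask = as_mask(mask)
    cfg = cfg or MorphologyConfig()
    cfg.validate()
    labels, n = ndimage.label(mask)
    if n == 0:
        warnings.warn("no lesion found: empty mask", stacklevel=2)
        return mask.copy()
    areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    main_lab = int(np.argmax(areas)) + 1
    main = labels == main_lab

    if n > 1:
        dist = ndimage.distance_transform_edt(~main)
        keep = main.copy()
        for lab in range(1, n + 1):
            if lab == main_lab:
                continue
            comp = labels == lab
            if areas[lab - 1] >= cfg.min_island_area and dist[comp].min() <= cfg.merge_distance:
                keep |= comp
        if keep.sum() > main.sum() and cfg.merge_distance > 1:
            keep = closing(keep, disk(max(1, cfg.merge_distance // 2)))
    else:
        keep = main

    if cfg.erosion_radius > 0:
        keep = erosion(keep, disk(cfg.erosion_radius))
    if cfg.dilation_radius > 0:
        keep = dilation(keep, disk(cfg.dilation_radius))
    # opening can re-split thin bridges; keep the dominant component only
    labels2, n2 = ndimage.label(keep)
    if n2 > 1:
        areas2 = ndimage.sum_labels(keep, labels2, index=np.arange(1, n2 + 1))
        keep = labels2 == (int(np.argmax(areas2)) + 1)
    if not keep.any():
        warnings.warn("no lesion found: opening removed all components", stacklevel=2)
    return keep


def smooth_boundary(mask: np.ndarray, window: int = 15) -> np.ndarray:
    """Moving-average smoothing of the traced boundary coordinates.

    The closed boundary is extracted as an ordered subpixel coordinate
    sequence, its row and column sequences are circularly averaged over
    ``window`` samples, and the smoothed polygon is re-rasterized.
    Requires a single-component mask (run :func:`manage_islands` first);
    ``window=1`` is the identity.
    """
    mask = as_mask(mask)
    if window < 1 or window % 2 == 0:
        raise ContractError(f"window must be odd >= 1, got {window}")
    _labels, n = ndimage.label(mask)
    if n == 0:
        return mask.copy()
    if n > 1:
        raise ContractError("smooth_boundary requires a single component; call manage_islands first")
    if window == 1:
        return mask.copy()

    contours = find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len)
    if len(contour) <= window:
        return mask.copy()
    kernel = np.ones(window) / window
    rows = np.convolve(np.concatenate([contour[:, 0]] * 3), kernel, mode="same")[
        len(contour) : 2 * len(contour)
    ]
    cols = np.convolve(np.concatenate([contour[:, 1]] * 3), kernel, mode="same")[
        len(contour) : 2 * len(contour)
    ]
    out = np.zeros_like(mask)
    rr, cc = polygon(rows, cols, shape=mask.shape)
    out[rr, cc] = True
    return out


def postprocess(
    mask: np.ndarray,
    corner_mask: np.ndarray | None = None,
    cfg: MorphologyConfig | None = None,
) -> np.ndarray:
    """Full cleanup: corner subtraction, hole filling, island management,
    boundary smoothing.  Never reintroduces pixels under the corner mask."""
    mask = as_mask(mask)
    cfg = cfg or MorphologyConfig()
    cfg.validate()
    out = mask.copy()
    if corner_mask is not None:
        corner_mask = as_mask(corner_mask, mask.shape)
        out &= ~corner_mask
    if cfg.fill_holes:
        out = fill_holes(out)
    out = manage_islands(out, cfg)
    if out.any():
        out = smooth_boundary(out, cfg.smooth_window)
    if corner_mask is not None:
        out &= ~corner_mask
    return out
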