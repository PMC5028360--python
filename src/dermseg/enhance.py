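"""Channel selection, enhancement and Otsu thresholding.

Dermoscopic lesions are pigmented and therefore darker than the
surrounding skin; on PH2-style images the blue channel separates lesion
from skin most cleanly, so ``blue`` is the pipeline default.  The other
selectors (luminance, per-channel, maximum-entropy channel, CIELAB
components) are kept for comparative runs.

This module also houses the Otsu threshold search used by every
thresholding stage, and the dark-corner detector that masks the
unilluminated rounded corners left by the dermatoscope lens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import rgb2lab

from .images import ContractError, GrayImage, as_rgb

__all__ = [
    "OtsuResult",
    "ChannelEntropy",
    "CHANNEL_SELECTORS",
    "luminance",
    "channel_entropy",
    "split_lab",
    "extract_channel",
    "otsu",
    "binarize",
    "corner_mask",
]

#: Rec. 601 luma weights for R, G, B.
_LUMA = (0.2989, 0.5870, 0.1140)

CHANNEL_SELECTORS = ("red", "green", "blue", "luminance", "max_entropy", "L", "a", "b")


@dataclass(frozen=True)
class OtsuResult:
    """Outcome of the exhaustive intra-class-variance minimization.

    ``threshold`` is the gray level (bin index in 0..254) minimizing
    ``w1*var1 + w2*var2``; ties break toward the smaller level.
    """

    threshold: int
    class_weights: tuple[float, float]
    class_variances: tuple[float, float]
    objective: float


@dataclass(frozen=True)
class ChannelEntropy:
    """Shannon entropy of each RGB channel histogram, in bits."""

    per_channel: tuple[float, float, float]
    argmax_channel: int


def luminance(img: np.ndarray) -> GrayImage:
    """Rec. 601 luminance, ``0.2989 R + 0.5870 G + 0.1140 B``, unrounded."""
    img = as_rgb(img)
    px = img.astype(np.float64)
    out = px[..., 0] * _LUMA[0] + px[..., 1] * _LUMA[1] + px[..., 2] * _LUMA[2]
    return GrayImage(out, (0.0, 255.0))


def channel_entropy(img: np.ndarray) -> ChannelEntropy:
    """Histogram entropy of each channel; winner breaks ties blue, then green.

    Entropy is the usual non-negative ``-sum p log2 p`` over the 256-bin
    histogram, so "highest entropy" means the channel spreading its mass
    over the most gray levels.
    """
    img = as_rgb(img)
    ents = []
    for c in range(3):
        counts = np.bincount(img[..., c].ravel(), minlength=256)
        p = counts[counts > 0] / counts.sum()
        ents.append(float(-(p * np.log2(p)).sum()))
    # preference order on exact ties: blue > green > red
    order = (2, 1, 0)
    winner = max(order, key=lambda c: (ents[c], -order.index(c)))
    return ChannelEntropy(tuple(ents), winner)


def split_lab(img: np.ndarray) -> tuple[GrayImage, GrayImage, GrayImage]:
    """CIE L*a*b* components under sRGB companding and D65 white point."""
    img = as_rgb(img)
    lab = rgb2lab(img)
    L = GrayImage(np.clip(lab[..., 0], 0, 100), (0.0, 100.0))
    a = GrayImage(np.clip(lab[..., 1], -128, 127), (-128.0, 127.0))
    b = GrayImage(np.clip(lab[..., 2], -128, 127), (-128.0, 127.0))
    return L, a, b


def extract_channel(img: np.ndarray, which: str = "blue") -> GrayImage:
    """Return the named single-channel image.

    ``which`` is one of ``red/green/blue`` (raw channels), ``luminance``,
    ``max_entropy`` (winner of :func:`channel_entropy`), or the CIELAB
    components ``L``, ``a``, ``b``.
    """
    img = as_rgb(img)
    if which in ("red", "green", "blue"):
        idx = ("red", "green", "blue").index(which)
        return GrayImage(img[..., idx].astype(np.float64), (0.0, 255.0))
    if which == "luminance":
        return luminance(img)
    if which == "max_entropy":
        idx = channel_entropy(img).argmax_channel
        return GrayImage(img[..., idx].astype(np.float64), (0.0, 255.0))
    if which in ("L", "a", "b"):
        return split_lab(img)[("L", "a", "b").index(which)]
    raise ContractError(f"unknown channel selector {which!r}; valid: {CHANNEL_SELECTORS}")


def _quantize(img: GrayImage, bins: int = 256) -> np.ndarray:
    """Map a gray image onto integer levels 0..bins-1 over its declared range."""
    lo, hi = img.value_range
    q = np.floor((img.pixels - lo) / (hi - lo) * bins).astype(np.int64)
    return np.clip(q, 0, bins - 1)


def otsu(img: GrayImage | np.ndarray) -> OtsuResult:
    """Exhaustive Otsu threshold: minimize the weighted intra-class variance.

    The image is quantized to 256 uniform bins over its declared range;
    every split ``t in [0, 254]`` (class 0 = levels <= t) with both
    classes non-empty is scored by ``w1*var1 + w2*var2`` and the smallest
    minimizing ``t`` is returned.

    Raises
    ------
    ContractError
        If the image has fewer than 2 distinct quantized levels
        ("degenerate histogram").
    """
    if not isinstance(img, GrayImage):
        img = GrayImage(np.asarray(img, dtype=np.float64))
    levels = _quantize(img)
    counts = np.bincount(levels.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(counts) < 2:
        raise ContractError("degenerate histogram: fewer than 2 distinct gray levels")

    total = counts.sum()
    vals = np.arange(256, dtype=np.float64)
    w1 = np.cumsum(counts)  # pixels at level <= t
    s1 = np.cumsum(counts * vals)
    ss1 = np.cumsum(counts * vals**2)
    w1t = w1[:-1]
    w2t = total - w1t
    valid = (w1t > 0) & (w2t > 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = s1[:-1] / w1t
        m2 = (s1[-1] - s1[:-1]) / w2t
        v1 = ss1[:-1] / w1t - m1**2
        v2 = (ss1[-1] - ss1[:-1]) / w2t - m2**2
    # clamp tiny negative values from catastrophic cancellation
    v1 = np.maximum(v1, 0.0)
    v2 = np.maximum(v2, 0.0)
    obj = (w1t / total) * v1 + (w2t / total) * v2
    obj[~valid] = np.inf

    t = int(np.argmin(obj))  # argmin returns the first (smallest) minimizer
    return OtsuResult(
        threshold=t,
        class_weights=(float(w1t[t] / total), float(w2t[t] / total)),
        class_variances=(float(v1[t]), float(v2[t])),
        objective=float(obj[t]),
    )


def threshold_value(img: GrayImage, t: int) -> float:
    """Convert an Otsu bin index to a value on the image's declared scale.

    The returned value is the upper edge of bin ``t``, so
    ``pixel <= value`` matches ``quantized_level <= t``.
    """
    lo, hi = img.value_range
    return lo + (hi - lo) * (t + 1) / 256.0


def binarize(img: GrayImage, t: float, dark_is_foreground: bool = True) -> np.ndarray:
    """Threshold a gray image into a boolean mask.

    With ``dark_is_foreground`` (the lesion convention: pigmented regions
    are darker than skin) the mask is ``pixel <= t``, else ``pixel > t``.
    """
    lo, hi = img.value_range
    if not lo <= t <= hi:
        raise ContractError(f"threshold {t} outside declared range {img.value_range}")
    return img.pixels <= t if dark_is_foreground else img.pixels > t


def corner_mask(img: GrayImage, opening_radius: int = 4) -> np.ndarray:
    """Binary mask of dark lens corners.

    Otsu-binarizes with dark-is-foreground, opens the dark mask with a
    small disc so thin dark structures (hairs) cannot bridge the lesion
    to the frame, and keeps only connected components touching an image
    corner pixel.  An image without dark corners (including a
    contrast-free one) yields an empty mask; the degenerate-histogram
    case emits a warning rather than failing, since corner-free images
    are the common case.
    """
    from skimage.morphology import disk, opening

    try:
        res = otsu(img)
    except ContractError:
        warnings.warn("degenerate histogram; returning empty corner mask", stacklevel=2)
        return np.zeros(img.shape, dtype=bool)
    dark = binarize(img, threshold_value(img, res.threshold), dark_is_foreground=True)
    if opening_radius > 0:
        dark = opening(dark, disk(opening_radius))
    labels, n = ndimage.label(dark)
    if n == 0:
        return np.zeros(img.shape, dtype=bool)
    h, w = img.shape
    corner_labels = {labels[0, 0], labels[0, w - 1], labels[h - 1, 0], labels[h - 1, w - 1]}
    corner_labels.discard(0)
    if not corner_labels:
        return np.zeros(img.shape, dtype=bool)
    return np.isin(labels, sorted(corner_labels))
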