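"""Lesion segmentation by thresholding the level-2 DWT approximation.

A two-level separable discrete wavelet transform of the enhanced blue
channel concentrates the lesion/skin contrast in the level-2
approximation band while shedding fine-scale artifacts (hair residue,
bubbles, skin texture) into the detail bands.  Otsu-thresholding that
quarter-resolution approximation and upsampling the mask back to full
resolution gives the raw lesion mask, which the postprocessing stage
then cleans.

Supported mother wavelets: haar (db1), db4, sym4, bior6.8 (the default
Cohen-Daubechies-Feauveau 6/8 biorthogonal pair) and cdf97 (the CDF 9/7
pair used by JPEG2000).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .enhance import binarize, otsu, threshold_value
from .images import ContractError, GrayImage, as_mask

__all__ = [
    "SUPPORTED_WAVELETS",
    "WaveletPyramid",
    "dwt2",
    "idwt2",
    "approximation",
    "segment_from_approximation",
    "segment_lesion",
]

#: public name -> PyWavelets name (cdf97 is the CDF 9/7 pair, known in
#: the bior family as bior4.4)
SUPPORTED_WAVELETS = {
    "haar": "haar",
    "db1": "haar",
    "db4": "db4",
    "sym4": "sym4",
    "bior6.8": "bior6.8",
    "cdf97": "bior4.4",
}

_BOUNDARY_MODE = "symmetric"  # half-sample symmetric extension, fixed for reproducibility


@dataclass(frozen=True)
class WaveletPyramid:
    """Multilevel 2-D DWT: per level an approximation A and details H, V, D.

    ``bands[k]`` holds level ``k+1``; band sizes halve (with
    filter-length-dependent padding under symmetric extension) per level.
    """

    levels: int
    bands: tuple[dict[str, np.ndarray], ...]
    wavelet_name: str
    boundary_mode: str
    original: np.ndarray  # level-0 approximation = the input image

    def band(self, level: int, which: str) -> np.ndarray:
        if not 1 <= level <= self.levels:
            raise ContractError(f"level {level} out of range 1..{self.levels}")
        return self.bands[level - 1][which]


def _pywt_name(wavelet_name: str) -> str:
    try:
        return SUPPORTED_WAVELETS[wavelet_name]
    except KeyError:
        raise ContractError(
            f"unsupported wavelet {wavelet_name!r}; supported: {sorted(SUPPORTED_WAVELETS)}"
        ) from None


def dwt2(img: GrayImage | np.ndarray, wavelet_name: str = "bior6.8", levels: int = 2) -> WaveletPyramid:
    """Multilevel separable 2-D DWT with symmetric boundary extension.

    The approximation of level ``l`` is re-decomposed to produce level
    ``l + 1``.
    """
    arr = img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=np.float64)
    if levels < 1:
        raise ContractError("levels must be >= 1")
    if min(arr.shape) < 2**levels:
        raise ContractError(f"image {arr.shape} too small for {levels} levels")
    name = _pywt_name(wavelet_name)
    bands = []
    a = arr
    for _ in range(levels):
        a, (h, v, d) = pywt.dwt2(a, name, mode=_BOUNDARY_MODE)
        bands.append({"A": a, "H": h, "V": v, "D": d})
    return WaveletPyramid(
        levels=levels,
        bands=tuple(bands),
        wavelet_name=wavelet_name,
        boundary_mode=_BOUNDARY_MODE,
        original=arr,
    )


def idwt2(pyr: WaveletPyramid) -> np.ndarray:
    """Invert the pyramid; reconstructs the input to numerical precision."""
    name = _pywt_name(pyr.wavelet_name)
    a = pyr.bands[-1]["A"]
    for lvl in range(pyr.levels, 0, -1):
        b = pyr.bands[lvl - 1]
        a = pywt.idwt2((a, (b["H"], b["V"], b["D"])), name, mode=pyr.boundary_mode)
        target = pyr.bands[lvl - 2]["H"].shape if lvl > 1 else pyr.original.shape
        a = a[: target[0], : target[1]]  # trim odd-size padding
    return a


def approximation(pyr: WaveletPyramid, level: int) -> np.ndarray:
    """The approximation band at ``level``; level 0 is the original image."""
    if level == 0:
        return pyr.original
    return pyr.band(level, "A")


def _coeff_offset(wavelet_name: str, levels: int) -> float:
    """Group delay of the multilevel lowpass path, in full-resolution pixels.

    Coefficient ``k`` at level ``levels`` is centered near input position
    ``2^levels * k - offset``.  Measured by decomposing 1-D impulses at
    every subsampling phase and averaging the energy centroids of the
    resulting coefficients (the phase average resolves the half-sample
    bias of short filters such as haar).  Cached per (wavelet, levels).
    """
    key = (wavelet_name, levels)
    if key not in _OFFSET_CACHE:
        name = _pywt_name(wavelet_name)
        stride = 2**levels
        n = 64 * stride
        offsets = []
        for phase in range(stride):  # average over subsampling phases
            sig = np.zeros(n)
            sig[n // 2 + phase] = 1.0
            a = sig
            for _ in range(levels):
                a, _d = pywt.dwt(a, name, mode=_BOUNDARY_MODE)
            w = a**2
            centroid = float((np.arange(a.size) * w).sum() / w.sum())
            offsets.append(centroid * stride - (n // 2 + phase))
        _OFFSET_CACHE[key] = float(np.mean(offsets))
    return _OFFSET_CACHE[key]


_OFFSET_CACHE: dict[tuple[str, int], float] = {}


def segment_from_approximation(
    a2: np.ndarray,
    original_shape: tuple[int, int],
    wavelet_name: str = "bior6.8",
    levels: int = 2,
    strategy: str = "otsu",
) -> np.ndarray:
    """Binarize a deep approximation band and upsample to full resolution.

    Dark-is-foreground (the lesion is darker than skin); ``strategy`` is
    ``"otsu"`` or ``"fixed:<v>"`` with ``v`` on the approximation-band
    scale (the lowpass gain is 2 per level, so intensity ``c`` appears as
    ``c * 2^levels``).  The coarse mask is expanded by nearest-neighbor,
    compensating the group delay of the lowpass filter path so the mask
    stays registered with the input.  Raises on a contrast-free band
    under Otsu.
    """
    a2 = np.asarray(a2, dtype=np.float64)
    if strategy == "otsu":
        gi = GrayImage(a2, (float(a2.min()), float(max(a2.max(), a2.min() + 1e-9))))
        try:
            res = otsu(gi)
        except ContractError:
            raise ContractError("no contrast at level 2: approximation band is constant") from None
        coarse = binarize(gi, threshold_value(gi, res.threshold), dark_is_foreground=True)
    elif strategy.startswith("fixed:"):
        coarse = a2 <= float(strategy.split(":", 1)[1])
    else:
        raise ContractError(f"unknown seg_threshold strategy {strategy!r}; valid: otsu, fixed:<v>")
    stride = 2**levels
    off = _coeff_offset(wavelet_name, levels)
    # half-up rounding (not rint's half-to-even) keeps the mapping
    # shift-equivariant: translating the input by one stride translates
    # the upsampled mask exactly
    rows = np.clip(np.floor((np.arange(original_shape[0]) + off) / stride + 0.5).astype(int), 0, coarse.shape[0] - 1)
    cols = np.clip(np.floor((np.arange(original_shape[1]) + off) / stride + 0.5).astype(int), 0, coarse.shape[1] - 1)
    return coarse[np.ix_(rows, cols)]


def segment_lesion(
    channel_img: GrayImage,
    corner_mask: np.ndarray | None = None,
    wavelet_name: str = "bior6.8",
    level: int = 2,
    strategy: str = "otsu",
) -> np.ndarray:
    """Raw full-resolution lesion mask from a preprocessed channel image.

    Pixels under the corner mask are replaced by the median intensity of
    the remaining skin before decomposition, so dark lens corners cannot
    drag the Otsu threshold on the approximation band; the corner region
    is also subtracted from the output.
    """
    px = channel_img.pixels.copy()
    if corner_mask is not None:
        corner_mask = as_mask(corner_mask, px.shape)
        if corner_mask.any():
            if corner_mask.all():
                raise ContractError("corner mask covers the whole image")
            px[corner_mask] = np.median(px[~corner_mask])
    pyr = dwt2(GrayImage(px, channel_img.value_range), wavelet_name, levels=level)
    a = approximation(pyr, level)
    mask = segment_from_approximation(a, px.shape, wavelet_name, level, strategy)
    if corner_mask is not None:
        mask &= ~corner_mask
    return mask
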