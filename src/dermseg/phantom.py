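"""Seeded synthetic dermoscopy phantoms with per-artifact ground truth.

A phantom emulates a PH2-style dermoscopic frame: a darker, soft-edged
elliptical lesion on lighter skin, dark curved hair strokes crossing both
lesion and skin, bright gel/water bubbles with darker rims, and the dark
rounded corners a round dermatoscope lens leaves on a rectangular sensor.
Every artifact comes with its own ground-truth mask, so each pipeline
stage can be scored in isolation without any external dataset.

The default canvas is 256x192, the PH2 768x560 aspect ratio scaled down
for fast test suites; the full size is available through the spec.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.draw import bezier_curve, disk
from skimage.morphology import dilation, footprint_rectangle

from .images import ContractError

__all__ = ["PhantomSpec", "PhantomCase", "generate_phantom", "generate_suite", "line_image"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic dermoscopic frame.

    The lesion ellipse (center, semi-axes) must fit inside the canvas;
    ``edge_softness`` is the Gaussian blur sigma (pixels) applied to the
    lesion's alpha map, emulating the smooth skin-to-lesion transition of
    real dermoscopy; ``corner_radius`` = 0 disables the dark lens corners.
    """

    height: int = 192
    width: int = 256
    skin_color: tuple[int, int, int] = (225, 165, 140)
    lesion_center: tuple[int, int] = (96, 128)
    lesion_axes: tuple[int, int] = (42, 58)
    lesion_color: tuple[int, int, int] = (115, 70, 50)
    edge_softness: float = 3.0
    n_hairs: int = 0
    hair_thickness: int = 2
    hair_color: tuple[int, int, int] = (55, 40, 35)
    n_bubbles: int = 0
    corner_radius: int = 0
    noise_sd: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ContractError(f"canvas too small: {self.height}x{self.width}")
        for name in ("skin_color", "lesion_color", "hair_color"):
            col = getattr(self, name)
            if not all(0 <= v <= 255 for v in col):
                raise ContractError(f"{name}={col} outside [0, 255]")
        r, c = self.lesion_center
        ar, ac = self.lesion_axes
        if ar <= 0 or ac <= 0:
            raise ContractError(f"lesion_axes={self.lesion_axes} must be positive")
        if not (ar <= r <= self.height - 1 - ar and ac <= c <= self.width - 1 - ac):
            raise ContractError(
                f"lesion ellipse (center={self.lesion_center}, axes={self.lesion_axes}) "
                f"does not fit inside {self.height}x{self.width} frame"
            )
        if self.edge_softness < 0:
            raise ContractError("edge_softness must be >= 0")
        if self.n_hairs < 0 or self.n_bubbles < 0:
            raise ContractError("artifact counts must be >= 0")
        if self.hair_thickness < 1:
            raise ContractError("hair_thickness must be >= 1")
        if self.corner_radius < 0:
            raise ContractError("corner_radius must be >= 0")
        if self.noise_sd < 0:
            raise ContractError("noise_sd must be >= 0")


@dataclass(frozen=True)
class PhantomCase:
    """A rendered phantom with its ground-truth masks."""

    image: np.ndarray  # (H, W, 3) uint8
    lesion_mask: np.ndarray  # bool
    hair_mask: np.ndarray  # bool
    corner_mask: np.ndarray  # bool
    spec: PhantomSpec


def _lesion_alpha(spec: PhantomSpec) -> np.ndarray:
    rr, cc = np.mgrid[0 : spec.height, 0 : spec.width].astype(np.float64)
    r0, c0 = spec.lesion_center
    ar, ac = spec.lesion_axes
    inside = ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0
    alpha = inside.astype(np.float64)
    if spec.edge_softness > 0:
        alpha = ndimage.gaussian_filter(alpha, spec.edge_softness)
    return alpha


def _corner_mask(spec: PhantomSpec) -> np.ndarray:
    """Four quarter-disc complements: the corner square minus the rounded lens arc."""
    r = spec.corner_radius
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    if r == 0:
        return mask
    rr, cc = np.mgrid[0:r, 0:r].astype(np.float64)
    block = (rr - (r - 1)) ** 2 + (cc - (r - 1)) ** 2 > r**2  # outside the arc
    mask[:r, :r] |= block
    mask[:r, -r:] |= block[:, ::-1]
    mask[-r:, :r] |= block[::-1, :]
    mask[-r:, -r:] |= block[::-1, ::-1]
    return mask


def _draw_hairs(canvas: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Stamp dark quadratic-curve strokes; returns the hair mask."""
    h, w = spec.height, spec.width
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(spec.n_hairs):
        # endpoints on opposite borders so strokes cross the frame (and often
        # the centered lesion — the hard case for segmentation)
        if rng.random() < 0.5:
            p0 = (int(rng.integers(0, h)), 0)
            p2 = (int(rng.integers(0, h)), w - 1)
        else:
            p0 = (0, int(rng.integers(0, w)))
            p2 = (h - 1, int(rng.integers(0, w)))
        p1 = (int(rng.integers(0, h)), int(rng.integers(0, w)))  # control point bends the hair
        rr, cc = bezier_curve(p0[0], p0[1], p1[0], p1[1], p2[0], p2[1], weight=1.0, shape=(h, w))
        stroke = np.zeros((h, w), dtype=bool)
        stroke[rr, cc] = True
        if spec.hair_thickness > 1:
            stroke = dilation(
                stroke, footprint_rectangle((spec.hair_thickness, spec.hair_thickness))
            )
        mask |= stroke
    canvas[mask] = np.asarray(spec.hair_color, dtype=np.float64)
    return mask


def _draw_bubbles(canvas: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> None:
    """Bright gel/water bubbles with slightly darker rims; no GT mask needed."""
    h, w = spec.height, spec.width
    for _ in range(spec.n_bubbles):
        radius = int(rng.integers(4, 10))
        r0 = int(rng.integers(radius, h - radius))
        c0 = int(rng.integers(radius, w - radius))
        rr, cc = disk((r0, c0), radius, shape=(h, w))
        canvas[rr, cc] = np.minimum(canvas[rr, cc] * 1.35 + 40, 255.0)
        rim_rr, rim_cc = disk((r0, c0), radius, shape=(h, w))
        rim = np.zeros((h, w), dtype=bool)
        rim[rim_rr, rim_cc] = True
        rim &= ~ndimage.binary_erosion(rim, iterations=2)
        canvas[rim] *= 0.75


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Render one phantom; deterministic for a fixed spec (seed included)."""
    spec.validate()
    # separate substreams: artifact placement and pixel noise, so two specs
    # differing only in artifact counts share the same noise field
    rng = np.random.default_rng([spec.seed, 0])
    noise_rng = np.random.default_rng([spec.seed, 1])
    alpha = _lesion_alpha(spec)
    skin = np.asarray(spec.skin_color, dtype=np.float64)
    lesion = np.asarray(spec.lesion_color, dtype=np.float64)
    canvas = skin[None, None, :] * (1 - alpha[..., None]) + lesion[None, None, :] * alpha[..., None]
    lesion_mask = alpha >= 0.5

    _draw_bubbles(canvas, spec, rng)
    hair_mask = _draw_hairs(canvas, spec, rng)

    corner = _corner_mask(spec)
    canvas[corner] = np.array([18.0, 14.0, 16.0])

    if spec.noise_sd > 0:
        canvas = canvas + noise_rng.normal(0.0, spec.noise_sd, canvas.shape)
    image = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return PhantomCase(image, lesion_mask, hair_mask, corner, spec)


def generate_suite(n: int, base_spec: PhantomSpec, seed: int) -> list[PhantomCase]:
    """``n`` phantoms with jittered lesion position, size and contrast.

    Jitter is drawn from a generator seeded by ``seed``; each case keeps
    its own derived seed in ``case.spec.seed`` so it can be regenerated
    independently.
    """
    if n < 1:
        raise ContractError(f"suite size must be >= 1, got {n}")
    base_spec.validate()
    rng = np.random.default_rng(seed)
    cases = []
    for _ in range(n):
        ar = max(8, int(round(base_spec.lesion_axes[0] * rng.uniform(0.75, 1.15))))
        ac = max(8, int(round(base_spec.lesion_axes[1] * rng.uniform(0.75, 1.15))))
        ar = min(ar, (base_spec.height - 2) // 2)
        ac = min(ac, (base_spec.width - 2) // 2)
        r0 = int(rng.integers(ar + 1, base_spec.height - 1 - ar))
        c0 = int(rng.integers(ac + 1, base_spec.width - 1 - ac))
        fade = rng.uniform(0.0, 0.25)  # contrast jitter: pull lesion toward skin
        lesion = tuple(
            int(round(lc * (1 - fade) + sc * fade))
            for lc, sc in zip(base_spec.lesion_color, base_spec.skin_color)
        )
        spec = replace(
            base_spec,
            lesion_center=(r0, c0),
            lesion_axes=(ar, ac),
            lesion_color=lesion,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cases.append(generate_phantom(spec))
    return cases


def line_image(
    angle_deg: float,
    shape: tuple[int, int] = (128, 128),
    thickness: int = 2,
    background: float = 200.0,
    line_value: float = 60.0,
) -> np.ndarray:
    """A dark straight line through the image center, for filter-bank probes.

    ``angle_deg`` is measured counterclockwise from the horizontal axis in
    standard orientation (0 = horizontal, 90 = vertical), matching the
    orientation convention of the directional hair filters.
    """
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    r0, c0 = (h - 1) / 2.0, (w - 1) / 2.0
    theta = np.deg2rad(angle_deg)
    # signed distance to the line through the center with direction
    # (cos t, -sin t) in (col, row); rows grow downward
    dist = np.abs((cc - c0) * np.sin(theta) + (rr - r0) * np.cos(theta))
    img = np.full(shape, background, dtype=np.float64)
    img[dist <= thickness / 2.0] = line_value
    return img
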