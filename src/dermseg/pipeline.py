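"""End-to-end lesion segmentation: the full staged method.

The pipeline runs, in order: dark-corner detection, hair removal
(enhancement, segmentation, inpainting), channel extraction (blue by
default), 2-level wavelet segmentation on the approximation band, and
morphological postprocessing.  Every stage can be toggled and every
parameter is carried in a :class:`PipelineConfig` that serializes to
YAML and round-trips bit-identically, so any result can be re-run
exactly.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .enhance import corner_mask as detect_corners
from .enhance import extract_channel
from .hair import DoGParams, remove_hairs
from .images import ContractError, GrayImage, as_rgb
from .metrics import EvalReport, evaluate_batch
from .postprocess import MorphologyConfig, postprocess
from .wavelet import SUPPORTED_WAVELETS, segment_lesion

__all__ = ["PipelineConfig", "SegmentationResult", "run", "run_batch", "compare_wavelets"]

log = logging.getLogger("dermseg")


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of the segmentation pipeline, in one serializable record."""

    channel: str = "blue"
    hair_removal: bool = True
    dog: DoGParams = field(default_factory=DoGParams)
    hair_strategy: str = "otsu"
    inpaint_iterations: int = 50
    inpaint_dilation: int = 2
    median_window: int = 3
    corner_removal: bool = True
    wavelet_name: str = "bior6.8"
    level: int = 2
    seg_threshold: str = "otsu"
    morphology: MorphologyConfig = field(default_factory=MorphologyConfig)
    seed: int = 0

    def to_yaml(self) -> str:
        d = asdict(self)
        d["dog"]["angles"] = list(d["dog"]["angles"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        dog = d.pop("dog", None)
        morph = d.pop("morphology", None)
        cfg = cls(**d)
        if dog is not None:
            dog["angles"] = tuple(float(a) for a in dog["angles"])
            cfg = replace(cfg, dog=DoGParams(**dog))
        if morph is not None:
            cfg = replace(cfg, morphology=MorphologyConfig(**morph))
        return cfg

    def validate(self) -> None:
        self.dog.validate()
        self.morphology.validate()
        if self.wavelet_name not in SUPPORTED_WAVELETS:
            raise ContractError(
                f"unsupported wavelet {self.wavelet_name!r}; supported: {sorted(SUPPORTED_WAVELETS)}"
            )
        if self.level < 1:
            raise ContractError("level must be >= 1")


@dataclass(frozen=True)
class SegmentationResult:
    """Final mask plus every intermediate needed to audit a run."""

    lesion_mask: np.ndarray
    wavelet_mask: np.ndarray  # raw mask before postprocessing
    channel_img: GrayImage
    cleaned_img: np.ndarray  # RGB after hair removal
    hair_mask: np.ndarray
    corner_mask: np.ndarray
    config_snapshot: str  # YAML, sufficient to re-run bit-identically

    @property
    def found_lesion(self) -> bool:
        return bool(self.lesion_mask.any())


def _stage(name: str, t0: float, mask_area: int | None = None) -> None:
    msg = f"stage={name} elapsed={time.perf_counter() - t0:.3f}s"
    if mask_area is not None:
        msg += f" mask_area={mask_area}"
    log.info(msg)


def run(img: np.ndarray, cfg: PipelineConfig | None = None) -> SegmentationResult:
    """Segment one dermoscopic image; deterministic for fixed (image, config)."""
    img = as_rgb(img)
    cfg = cfg or PipelineConfig()
    cfg.validate()

    t0 = time.perf_counter()
    if cfg.corner_removal:
        corners = detect_corners(extract_channel(img, "blue"))
    else:
        corners = np.zeros(img.shape[:2], dtype=bool)
    _stage("corner_mask", t0, int(corners.sum()))

    t0 = time.perf_counter()
    if cfg.hair_removal:
        cleaned, hair = remove_hairs(
            img,
            cfg.dog,
            strategy=cfg.hair_strategy,
            iterations=cfg.inpaint_iterations,
            window=cfg.median_window,
            dilation_radius=cfg.inpaint_dilation,
            exclude=corners if corners.any() else None,
        )
    else:
        cleaned, hair = img.copy(), np.zeros(img.shape[:2], dtype=bool)
    _stage("hair_removal", t0, int(hair.sum()))

    t0 = time.perf_counter()
    channel = extract_channel(cleaned, cfg.channel)
    _stage("channel", t0)

    t0 = time.perf_counter()
    raw = segment_lesion(channel, corners, cfg.wavelet_name, cfg.level, cfg.seg_threshold)
    _stage("wavelet_seg", t0, int(raw.sum()))

    t0 = time.perf_counter()
    final = postprocess(raw, corners, cfg.morphology)
    _stage("postprocess", t0, int(final.sum()))
    if not final.any():
        log.warning("no lesion found")

    return SegmentationResult(
        lesion_mask=final,
        wavelet_mask=raw,
        channel_img=channel,
        cleaned_img=cleaned,
        hair_mask=hair,
        corner_mask=corners,
        config_snapshot=cfg.to_yaml(),
    )


def _read_image(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    return as_rgb(iio.imread(path)[..., :3])


def _write_mask(path: Path, mask: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, (mask.astype(np.uint8) * 255))


def run_batch(
    images_dir: str | Path,
    cfg: PipelineConfig | None = None,
    gt_dir: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> EvalReport | None:
    """Segment every readable image in a directory; optionally score vs GT.

    Masks are written to ``out_dir`` (as ``<stem>_mask.png``, 0/255).
    Ground-truth masks are matched by filename stem.  Unreadable inputs
    are logged and skipped.
    """
    images_dir = Path(images_dir)
    paths = sorted(
        p for p in images_dir.iterdir()
        if p.suffix.lower() in (".png", ".jpg", ".jpeg", ".bmp")
    )
    if not paths:
        raise ContractError(f"no readable images in {images_dir}")
    cfg = cfg or PipelineConfig()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    pairs = []
    for p in paths:
        try:
            img = _read_image(p)
            res = run(img, cfg)
        except Exception as e:  # noqa: BLE001 - batch runs skip bad inputs
            log.warning("skipping %s: %s", p.name, e)
            continue
        if out_dir is not None:
            _write_mask(out_dir / f"{p.stem}_mask.png", res.lesion_mask)
        if gt_dir is not None:
            gt_path = _match_gt(Path(gt_dir), p.stem)
            if gt_path is not None:
                import imageio.v3 as iio

                gt = iio.imread(gt_path)
                if gt.ndim == 3:
                    gt = gt[..., 0]
                pairs.append((res.lesion_mask, gt > 127, p.stem))
    if gt_dir is not None and pairs:
        return evaluate_batch(pairs)
    return None


def _match_gt(gt_dir: Path, stem: str) -> Path | None:
    for suffix in (".png", ".bmp", ".jpg", ".jpeg"):
        for candidate in (gt_dir / f"{stem}{suffix}", gt_dir / f"{stem}_lesion{suffix}"):
            if candidate.exists():
                return candidate
    return None


def compare_wavelets(
    cases,
    cfg: PipelineConfig | None = None,
    families: tuple[str, ...] = ("haar", "db4", "sym4", "bior6.8", "cdf97"),
):
    """Run the pipeline once per wavelet family over a phantom suite.

    Returns a pandas DataFrame with one row per family and columns
    ATDR/AFPR/AEP/DICE (percent scale), the comparison grid used to pick
    the default mother wavelet.
    """
    import pandas as pd

    cfg = cfg or PipelineConfig()
    rows = []
    for fam in families:
        fam_cfg = replace(cfg, wavelet_name=fam)
        pairs = [
            (run(case.image, fam_cfg).lesion_mask, case.lesion_mask, f"case_{i:03d}")
            for i, case in enumerate(cases)
        ]
        rep = evaluate_batch(pairs)
        rows.append(
            {"wavelet": fam, "ATDR": rep.atdr, "AFPR": rep.afpr, "AEP": rep.aep, "DICE": rep.mean_dice}
        )
    return pd.DataFrame(rows).set_index("wavelet")
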