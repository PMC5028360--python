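"""Pixelwise segmentation scores against a manual ground-truth mask.

All rates are fractions in [0, 1] on the records and percentages on the
report averages, matching how dermoscopy segmentation tables are usually
printed.  ``tdr`` (true detection rate) and ``tpr`` are synonyms here,
``fpr`` is false positives *relative to the ground-truth area* (the
convention used for AFPR tables in this literature, distinct from the
standard fall-out, which is reported separately as ``fallout``), and
``ep`` is the error probability ``(FPR + FNR) / (TPR + FPR + TNR + FNR)``
computed from the standard confusion-matrix rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .images import ContractError, as_mask

__all__ = ["ConfusionCounts", "EvalRecord", "EvalReport", "confusion", "evaluate", "evaluate_batch"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def gt_area(self) -> int:
        return self.tp + self.fn

    @property
    def pred_area(self) -> int:
        return self.tp + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class EvalRecord:
    """Per-image rates (fractions in [0, 1]) plus the underlying counts."""

    tdr: float
    fpr: float
    fallout: float
    fnr: float
    tnr: float
    tpr: float
    ep: float
    dice: float
    counts: ConfusionCounts
    image_id: str = ""


@dataclass(frozen=True)
class EvalReport:
    """Batch result: per-image records and percent-scale averages."""

    records: tuple[EvalRecord, ...]
    failures: tuple[tuple[str, str], ...] = ()  # (image_id, reason)

    @property
    def atdr(self) -> float:
        return 100.0 * float(np.mean([r.tdr for r in self.records]))

    @property
    def afpr(self) -> float:
        return 100.0 * float(np.mean([r.fpr for r in self.records]))

    @property
    def aep(self) -> float:
        return 100.0 * float(np.mean([r.ep for r in self.records]))

    @property
    def mean_dice(self) -> float:
        return 100.0 * float(np.mean([r.dice for r in self.records]))


def confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Exact counts of the four joint pixel outcomes."""
    pred = as_mask(pred)
    gt = as_mask(gt, pred.shape)
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    return ConfusionCounts(tp, fp, fn, tn)


def evaluate(pred: np.ndarray, gt: np.ndarray, image_id: str = "") -> EvalRecord:
    """Score one predicted mask against its ground truth.

    * ``tdr = tpr = #(SR & GT) / #GT``
    * ``fpr = #(SR & ~GT) / #GT`` (ground-truth-normalized, as in AFPR
      tables); ``fallout = fp / (fp + tn)`` is the standard rate
    * ``fnr = fn / #GT``; ``tnr = tn / (tn + fp)``
    * ``ep = (fpr_rate + fnr) / (tpr + fpr_rate + tnr + fnr)`` with
      ``fpr_rate`` the standard fall-out, so ``ep`` is a proper error
      probability in [0, 1]
    * ``dice = 2 tp / (pred_area + gt_area)``
    """
    c = confusion(pred, gt)
    if c.gt_area == 0:
        raise ContractError("ground truth empty")
    tdr = c.tp / c.gt_area
    fpr = c.fp / c.gt_area
    fnr = c.fn / c.gt_area
    fallout = c.fp / (c.fp + c.tn) if (c.fp + c.tn) else 0.0
    tnr = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0
    tpr = tdr
    denom = tpr + fallout + tnr + fnr
    ep = (fallout + fnr) / denom if denom else 0.0
    dice = 2 * c.tp / (c.pred_area + c.gt_area) if (c.pred_area + c.gt_area) else 0.0
    return EvalRecord(
        tdr=tdr, fpr=fpr, fallout=fallout, fnr=fnr, tnr=tnr, tpr=tpr, ep=ep, dice=dice,
        counts=c, image_id=image_id,
    )


def evaluate_batch(pairs) -> EvalReport:
    """Evaluate ``(pred, gt, image_id)`` triples; averages are unweighted means.

    Pairs that fail (e.g. empty ground truth) are excluded from the
    averages and recorded in ``report.failures``.
    """
    pairs = list(pairs)
    if not pairs:
        raise ContractError("need at least one (pred, gt, id) pair")
    records, failures = [], []
    for pred, gt, image_id in pairs:
        try:
            records.append(evaluate(pred, gt, image_id))
        except ContractError as e:
            failures.append((image_id, str(e)))
    if not records:
        raise ContractError("every pair failed evaluation")
    return EvalReport(records=tuple(records), failures=tuple(failures))
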