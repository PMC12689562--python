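"""Segmentation metrics, binary cross-entropy loss, and the poly LR schedule.

Metrics follow the standard confusion-count definitions for two classes
(lesion foreground, skin background):

    Acc       = (TP + TN) / (TP + TN + FP + FN)
    IoU_c     = TP_c / (TP_c + FP_c + FN_c),  MIoU = mean over both classes
    Recall    = TP / (TP + FN)        (foreground)
    Precision = TP / (TP + FP)        (foreground)
    F1        = harmonic mean of Precision and Recall
    MRecall   = mean of the per-class recalls

Zero-denominator convention: a class absent from both prediction and ground
truth scores 1 (absence was predicted correctly), otherwise 0.

Confusion counts pool over a dataset before computing aggregate metrics
(micro-averaging); per-image metrics are reported alongside.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import Tensor

__all__ = ["ConfusionCounts", "MetricReport", "confusion_counts",
           "metrics_from_counts", "bce_loss", "poly_lr"]

log = logging.getLogger(__name__)

_EPS = 1e-7


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Exhaustive pixel tally of a binary prediction against ground truth."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    for name, arr in (("pred", pred), ("gt", gt)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} mask must be binary (values in {{0, 1}})")
    pred = pred.astype(bool)
    gt = gt.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(pred & gt)),
        tn=int(np.count_nonzero(~pred & ~gt)),
        fp=int(np.count_nonzero(pred & ~gt)),
        fn=int(np.count_nonzero(~pred & gt)),
    )


def _safe_ratio(num: int, den: int, absent_in_both: bool) -> float:
    if den == 0:
        return 1.0 if absent_in_both else 0.0
    return num / den


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float]:
    """Five metrics from pooled confusion counts (two classes)."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    fg_absent = (c.tp + c.fp + c.fn) == 0   # lesion absent in pred and gt
    bg_absent = (c.tn + c.fn + c.fp) == 0

    acc = (c.tp + c.tn) / c.total
    iou_fg = _safe_ratio(c.tp, c.tp + c.fp + c.fn, fg_absent)
    iou_bg = _safe_ratio(c.tn, c.tn + c.fn + c.fp, bg_absent)
    miou = 0.5 * (iou_fg + iou_bg)
    recall_fg = _safe_ratio(c.tp, c.tp + c.fn, fg_absent)
    recall_bg = _safe_ratio(c.tn, c.tn + c.fp, bg_absent)
    precision = _safe_ratio(c.tp, c.tp + c.fp, fg_absent)
    if precision + recall_fg > 0:
        f1 = 2 * precision * recall_fg / (precision + recall_fg)
    else:
        f1 = 0.0
    return {"miou": miou, "acc": acc, "f1": f1,
            "mrecall": 0.5 * (recall_fg + recall_bg), "precision": precision}


@dataclass
class MetricReport:
    per_image: list[dict] = field(default_factory=list)
    aggregate: dict[str, float] = field(default_factory=dict)

    METRIC_KEYS = ("miou", "acc", "f1", "mrecall", "precision")

    @classmethod
    def from_pairs(cls, items: list[tuple[str, np.ndarray, np.ndarray]]) -> "MetricReport":
        """Build from (id, pred_mask, gt_mask) triples, pooling counts."""
        report = cls()
        pooled = ConfusionCounts(0, 0, 0, 0)
        for image_id, pred, gt in items:
            c = confusion_counts(pred, gt)
            if c.tp + c.fp + c.fn == 0:
                log.info("image %s: lesion class absent in both masks", image_id)
            row = {"id": image_id, **metrics_from_counts(c),
                   "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn}
            report.per_image.append(row)
            pooled = pooled + c
        report.aggregate = metrics_from_counts(pooled)
        return report

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"per_image": self.per_image, "aggregate": self.aggregate}, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "MetricReport":
        d = json.loads(Path(path).read_text())
        return cls(per_image=d["per_image"], aggregate=d["aggregate"])

    def to_csv(self, path: str | Path) -> None:
        cols = ["id", *self.METRIC_KEYS, "tp", "tn", "fp", "fn"]
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=cols)
            writer.writeheader()
            for row in self.per_image:
                writer.writerow(row)
            writer.writerow({"id": "aggregate",
                             **{k: self.aggregate[k] for k in self.METRIC_KEYS}})


def bce_loss(p, y):
    """Mean binary cross-entropy, -mean(y log p + (1-y) log(1-p)).

    ``p`` holds probabilities (clamped to [1e-7, 1 - 1e-7]); ``y`` holds
    binary labels.  Accepts either plain ndarrays (returns a float, for
    evaluation) or autodiff tensors for ``p`` (returns a Tensor, for
    training).
    """
    y_data = y.data if isinstance(y, Tensor) else np.asarray(y, dtype=np.float64)
    if not np.isin(y_data, (0.0, 1.0)).all():
        raise ValueError("labels must be binary (0 or 1)")
    if isinstance(p, Tensor):
        p = p.clip(_EPS, 1.0 - _EPS)
        y_t = y if isinstance(y, Tensor) else Tensor(y_data)
        return -((y_t * p.log() + (1.0 - y_t) * (1.0 - p).log()).mean())
    p = np.clip(np.asarray(p, dtype=np.float64), _EPS, 1.0 - _EPS)
    return float(-np.mean(y_data * np.log(p) + (1.0 - y_data) * np.log(1.0 - p)))


def poly_lr(iteration: int, max_iterations: int, base_lr: float = 7e-3,
            power: float = 0.9) -> float:
    """Polynomial decay: base_lr * (1 - iteration / max_iterations)^power."""
    if base_lr <= 0:
        raise ValueError("base_lr must be positive")
    if iteration < 0:
        raise ValueError("iteration must be non-negative")
    if iteration > max_iterations:
        warnings.warn(f"iteration {iteration} exceeds max_iterations "
                      f"{max_iterations}; learning rate clamped to 0")
        return 0.0
    return base_lr * (1.0 - iteration / max_iterations) ** power
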