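"""Evaluation arithmetic: confusion metrics, counting accuracy, IoU/Dice, matching.

The 2x2 confusion matrix follows the crop-inspection convention: rows are
the real class, columns the predicted class, with cells TN (true normal),
FD (false damaged), FN (false normal) and TD (true damaged). Damaged is the
positive class, so

    Acc = (TN + TD) / total,  P = TD / (TD + FD),
    R = TD / (FN + TD),       F1 = 2 P R / (P + R),

all expressed as percentages. Counting accuracy is 100 x detected / actual.
Segmentation quality uses mask overlap: IoU = |A n B| / |A u B| and
Dice = 2 |A n B| / (|A| + |B|).

Predicted instances are matched one-to-one to ground-truth kernels greedily
by descending IoU (floor 0.5 by default); unmatched ground-truth kernels are
tallied as missed detections and kept out of the classification metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_metrics",
    "counting_accuracy",
    "mask_overlap",
    "match_instances",
]


@dataclass
class ConfusionCounts:
    """TN / TD / FN / FD tallies; damaged is the positive class."""

    TN: int = 0
    TD: int = 0
    FN: int = 0
    FD: int = 0

    def __post_init__(self):
        if min(self.TN, self.TD, self.FN, self.FD) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TN + self.TD + self.FN + self.FD

    def add(self, true_label: str, pred_label: str) -> None:
        damaged_true = true_label == "damaged"
        damaged_pred = pred_label == "damaged"
        if damaged_true and damaged_pred:
            self.TD += 1
        elif damaged_true:
            self.FN += 1
        elif damaged_pred:
            self.FD += 1
        else:
            self.TN += 1


@dataclass
class MetricReport:
    """Percent-scale classification metrics plus counting and overlap scores.

    Metrics with zero denominators are ``None`` (undefined), never coerced.
    """

    acc: float | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    counting_accuracy: float | None = None
    iou: float | None = None
    dice: float | None = None
    n_kernels: int = 0
    n_missed: int = 0
    extra: dict = field(default_factory=dict)


def confusion_metrics(c: ConfusionCounts) -> tuple[
    float | None, float | None, float | None, float | None
]:
    """(Acc, P, R, F1) in percent; ``None`` where the denominator is zero."""
    acc = 100.0 * (c.TN + c.TD) / c.total if c.total else None
    p = 100.0 * c.TD / (c.TD + c.FD) if (c.TD + c.FD) else None
    r = 100.0 * c.TD / (c.FN + c.TD) if (c.FN + c.TD) else None
    f1 = None
    if p is not None and r is not None and (p + r) > 0:
        f1 = 2.0 * p * r / (p + r)
    elif p is not None and r is not None:
        f1 = 0.0 if (p == 0 and r == 0) else None
    return acc, p, r, f1


def counting_accuracy(actual: int, detected: int) -> float:
    """100 x detected / actual; the manual count must be positive."""
    if actual <= 0:
        raise ValueError("actual count must be positive")
    return 100.0 * detected / actual


def mask_overlap(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """(IoU, Dice) of two boolean masks; two empty masks overlap perfectly."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    inter = int(np.logical_and(pred, truth).sum())
    a, b = int(pred.sum()), int(truth.sum())
    union = a + b - inter
    if union == 0:
        return 1.0, 1.0
    iou = inter / union
    dice = 2.0 * inter / (a + b)
    return iou, dice


def _instance_bboxes(labels: np.ndarray) -> dict[int, tuple[slice, slice]]:
    from scipy import ndimage

    out = {}
    objs = ndimage.find_objects(labels)
    for lab, sl in enumerate(objs, start=1):
        if sl is not None:
            out[lab] = sl
    return out


def match_instances(
    pred_labels: np.ndarray,
    truth_masks,
    truth_labels: list[str],
    pred_classes: list[str] | None = None,
    iou_floor: float = 0.5,
) -> tuple[ConfusionCounts, list[float], int, list[tuple[int, int]]]:
    """Greedy one-to-one IoU matching of predicted instances to ground truth.

    Parameters
    ----------
    pred_labels : int label map (0 background, 1..K predicted instances)
    truth_masks : sequence of ground-truth kernel masks; each either a dense
        boolean array or an object with ``dense(shape)`` / ``bbox`` attributes
        (the synthetic generator's patch masks).
    truth_labels : per-kernel true damage labels.
    pred_classes : per-predicted-instance damage labels, indexed by label-1;
        when omitted every matched pair counts as correctly classified.
    iou_floor : minimum IoU for a valid match, in (0, 1).

    Returns
    -------
    (confusion, matched IoUs, number of unmatched ground-truth kernels,
    list of (pred_label, truth_index) matches).
    """
    if not 0 < iou_floor < 1:
        raise ValueError("iou_floor must lie in (0, 1)")
    pred_labels = np.asarray(pred_labels)
    n_pred = int(pred_labels.max())
    pred_areas = np.bincount(pred_labels.ravel(), minlength=n_pred + 1)

    candidates = []  # (iou, pred_label, truth_index)
    for ti, tm in enumerate(truth_masks):
        if hasattr(tm, "bbox_slices"):
            sl = tm.bbox_slices
            patch = tm.patch
        else:
            tm = np.asarray(tm, dtype=bool)
            rr, cc = np.nonzero(tm)
            if rr.size == 0:
                continue
            sl = (slice(rr.min(), rr.max() + 1), slice(cc.min(), cc.max() + 1))
            patch = tm[sl]
        sub = pred_labels[sl]
        t_area = int(patch.sum())
        labs, counts = np.unique(sub[patch], return_counts=True)
        for lab, inter in zip(labs, counts):
            if lab <= 0:
                continue
            union = pred_areas[lab] + t_area - inter
            iou = inter / union if union else 0.0
            if iou >= iou_floor:
                candidates.append((float(iou), int(lab), ti))
    candidates.sort(key=lambda t: -t[0])

    used_pred: set[int] = set()
    used_truth: set[int] = set()
    matches: list[tuple[int, int]] = []
    ious: list[float] = []
    confusion = ConfusionCounts()
    for iou, lab, ti in candidates:
        if lab in used_pred or ti in used_truth:
            continue
        used_pred.add(lab)
        used_truth.add(ti)
        matches.append((lab, ti))
        ious.append(iou)
        true_lab = truth_labels[ti]
        pred_lab = pred_classes[lab - 1] if pred_classes is not None else true_lab
        confusion.add(true_lab, pred_lab)
    n_missed = len(truth_labels) - len(used_truth)
    return confusion, ious, n_missed, matches
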