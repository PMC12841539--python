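"""End-to-end orchestration and the four ablation configurations.

The full method (variant ``W&C-SVM``) runs: preprocessing (grayscale, Otsu,
opening+closing) -> marker-based watershed on the distance field (coarse
separation) -> convexity-defect cutting per watershed region (fine
separation) -> minimum-area filtering -> shape features -> SVM
classification.

Ablation variants switch stages off:

- ``Raw-W&C-SVM``  skips preprocessing: channel-mean grayscale, a fixed
  midrange threshold and no morphology, so speckle noise survives as false
  contours;
- ``C-SVM``        skips the watershed pre-segmentation; defect cutting is
  applied directly to the binarized connected components;
- ``W-SVM``        skips the convexity-defect refinement.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import preprocess as pp
from . import watershed as ws
from .evaluate import MetricReport, confusion_metrics, counting_accuracy, match_instances
from .features import KernelRecord, features_from_mask
from .hull import split_at_defects, trace_boundary
from .svm import SvmConfig, SvmModel, fit as svm_fit
from .synthetic import SceneSpec, generate_scene

__all__ = [
    "VARIANTS",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "build_training_table",
    "train_and_evaluate",
    "ablation_configs",
]

logger = logging.getLogger(__name__)

VARIANTS = ("W&C-SVM", "Raw-W&C-SVM", "C-SVM", "W-SVM")

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class PipelineConfig:
    """Stage switches and every tunable parameter of the pipeline."""

    variant: str = "W&C-SVM"
    se_shape: str = "ellipse"
    se_size: int = 3
    sigma: float = 1.5
    peak_fraction: float = 0.4
    min_marker_area: int = 9
    depth_threshold: float = 8.0
    min_area: float | None = None  # absolute; None -> fraction of median
    min_area_fraction: float = 0.15
    iou_floor: float = 0.5
    height_source: str = "distance"  # or "gradient"
    svm: SvmConfig = field(default_factory=SvmConfig)
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.height_source not in ("distance", "gradient"):
            raise ValueError("height_source must be 'distance' or 'gradient'")


@dataclass
class PipelineResult:
    """Output of one pipeline run on a single image."""

    labels: np.ndarray  # final instance label map (0 background)
    records: list[KernelRecord]
    count: int
    mask: np.ndarray
    stage_log: dict


def _binarize_stage(image: np.ndarray, config: PipelineConfig) -> np.ndarray:
    if config.variant == "Raw-W&C-SVM":
        gray = image.mean(axis=2) if image.ndim == 3 else np.asarray(image, float)
        t = 0.5 * (float(gray.min()) + float(gray.max()))
        return gray > t
    gray = pp.to_grayscale(image) if np.asarray(image).ndim == 3 else np.asarray(image)
    t, _ = pp.otsu_threshold(gray)
    mask = pp.binarize(gray, t)
    se = pp.structuring_element(config.se_shape, config.se_size)
    return pp.clean_mask(mask, se)


def _watershed_stage(mask: np.ndarray, image, config: PipelineConfig) -> np.ndarray:
    if config.variant == "C-SVM":
        labels, _ = ndimage.label(mask, structure=_EIGHT)
        return labels.astype(np.int32)
    height = None
    if config.height_source == "gradient":
        gray = pp.to_grayscale(image) if np.asarray(image).ndim == 3 else np.asarray(image)
        height = ws.smooth_gradient(ws.sobel_gradient(gray), config.sigma).magnitude
    return ws.segment_mask(
        mask,
        peak_fraction=config.peak_fraction,
        min_marker_area=config.min_marker_area,
        height=height,
    )


def _refine_stage(labels: np.ndarray, config: PipelineConfig) -> np.ndarray:
    """Apply convexity-defect cutting inside each labelled region; relabel."""
    out = np.zeros_like(labels, dtype=np.int32)
    next_label = 1
    for l, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        region = labels[sl] == l
        if not region.any():
            continue
        cut, _ = split_at_defects(region, depth_threshold=config.depth_threshold)
        pieces, n = ndimage.label(cut, structure=_EIGHT)
        for p in range(1, n + 1):
            out[sl][pieces == p] = next_label
            next_label += 1
    return out


def _relabel(labels: np.ndarray) -> np.ndarray:
    u = np.unique(labels)
    u = u[u > 0]
    lut = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    lut[u] = np.arange(1, u.size + 1)
    return lut[labels]


def run_pipeline(
    image: np.ndarray, config: PipelineConfig | None = None, model: SvmModel | None = None
) -> PipelineResult:
    """Run the configured pipeline variant on one RGB or grayscale image.

    Returns the final instance label map, one feature record per surviving
    instance (classified when ``model`` is given) and the object count.
    """
    config = config or PipelineConfig()
    log: dict = {"variant": config.variant, "seed": config.seed}
    t0 = time.perf_counter()

    mask = _binarize_stage(image, config)
    if not mask.any():
        raise ValueError("empty foreground after binarization")
    log["foreground_px"] = int(mask.sum())

    labels = _watershed_stage(mask, image, config)
    log["watershed_regions"] = int(len(np.unique(labels[labels > 0])))

    if config.variant != "W-SVM":
        labels = _refine_stage(labels, config)
    log["post_refine_regions"] = int(len(np.unique(labels[labels > 0])))

    # minimum-area filter: suppress debris and cut slivers
    areas = np.bincount(labels.ravel())
    region_areas = areas[1:][areas[1:] > 0]
    if config.min_area is not None:
        min_area = config.min_area
    elif region_areas.size:
        min_area = config.min_area_fraction * float(np.median(region_areas))
    else:
        min_area = 0.0
    log["min_area"] = float(min_area)
    drop = np.flatnonzero(areas < min_area)
    if drop.size:
        labels = np.where(np.isin(labels, drop), 0, labels)
    labels = _relabel(labels)

    records: list[KernelRecord] = []
    for i, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        region = labels[sl] == i
        try:
            rec = features_from_mask(region, record_id=i - 1)
        except ValueError:  # degenerate sliver
            continue
        records.append(rec)
    if model is not None and records:
        for rec, lab in zip(records, model.predict(records)):
            rec.label = lab
    # the count is the number of surviving contours; degenerate slivers
    # (single pixels in the Raw variant with min_area 0) count but carry no
    # feature record
    count = int(labels.max())
    log["count"] = count
    log["elapsed_s"] = round(time.perf_counter() - t0, 3)
    logger.info("pipeline %s: %s", config.variant, log)
    return PipelineResult(
        labels=labels, records=records, count=count, mask=mask, stage_log=log
    )


def evaluate_scene(
    image: np.ndarray,
    gt,
    config: PipelineConfig,
    model: SvmModel | None,
) -> tuple[PipelineResult, MetricReport]:
    """Run the pipeline on a generated scene and score it against ground truth."""
    res = run_pipeline(image, config, model)
    pred_classes = [r.label for r in res.records] if model is not None else None
    # records are indexed by label-1 and every label has a record unless a
    # degenerate sliver was dropped; guard by rebuilding the aligned list
    if pred_classes is not None:
        aligned = ["intact"] * int(res.labels.max())
        for r, lab in zip(res.records, pred_classes):
            aligned[r.id] = lab
        pred_classes = aligned
    confusion, ious, n_missed, _ = match_instances(
        res.labels,
        gt.instance_masks,
        gt.damage_labels,
        pred_classes=pred_classes,
        iou_floor=config.iou_floor,
    )
    acc, p, r, f1 = confusion_metrics(confusion)
    report = MetricReport(
        acc=acc,
        precision=p,
        recall=r,
        f1=f1,
        counting_accuracy=counting_accuracy(gt.true_count, res.count),
        iou=float(np.mean(ious)) if ious else None,
        dice=float(np.mean([2 * i / (1 + i) for i in ious])) if ious else None,
        n_kernels=confusion.total,
        n_missed=n_missed,
        extra={"confusion": confusion},
    )
    return res, report


def build_training_table(
    scenes: list[tuple[np.ndarray, object]], config: PipelineConfig
):
    """Feature table for classifier training, in the segmentation domain.

    Each training scene is segmented by the configured pipeline; segmented
    instances are matched one-to-one to annotated kernels by IoU and take
    the annotation's intact/damaged label. Training on segmented (rather
    than annotation-mask) features keeps the classifier in the same feature
    domain it will see at prediction time — a kernel that loses pixels to a
    watershed line or an adhesion overlap looks the same in both phases.
    """
    import pandas as pd

    from .features import FEATURE_NAMES

    rows = []
    for image, gt in scenes:
        res = run_pipeline(image, config)
        _, _, _, matches = match_instances(
            res.labels, gt.instance_masks, gt.damage_labels,
            iou_floor=config.iou_floor,
        )
        by_label = {r.id + 1: r for r in res.records}
        for lab, ti in matches:
            rec = by_label.get(lab)
            if rec is None:
                continue
            rows.append(
                {**{n: getattr(rec, n) for n in FEATURE_NAMES},
                 "label": gt.damage_labels[ti]}
            )
    return pd.DataFrame(rows)


def train_and_evaluate(
    scene_specs: list[SceneSpec],
    config: PipelineConfig | None = None,
    split_fraction: float = 0.8,
) -> MetricReport:
    """Image-level 80/20 protocol on a batch of synthetic scenes.

    Scenes are split at the image level; the classifier is fitted on
    pipeline-segmented kernels of the training scenes only (labels carried
    over from the annotation by IoU matching), then the full pipeline runs
    on each held-out scene and is scored against its ground truth.
    Deterministic for fixed specs and config.
    """
    config = config or PipelineConfig()
    n = len(scene_specs)
    n_train = int(round(split_fraction * n))
    if n_train < 1 or n - n_train < 1:
        raise ValueError("need at least one scene in each split")
    order = np.random.default_rng(config.seed).permutation(n)
    train_ids = set(order[:n_train].tolist())

    train_scenes = []
    test_scenes = []
    for i, spec in enumerate(scene_specs):
        image, gt = generate_scene(spec)
        (train_scenes if i in train_ids else test_scenes).append((image, gt))
    train_table = build_training_table(train_scenes, config)
    if train_table.empty or train_table["label"].nunique() < 2:
        raise ValueError("training scenes did not yield both kernel classes")
    model = svm_fit(train_table, config.svm)

    from .evaluate import ConfusionCounts

    total = ConfusionCounts()
    count_accs, all_ious, missed, n_match = [], [], 0, 0
    for image, gt in test_scenes:
        _, rep = evaluate_scene(image, gt, config, model)
        c = rep.extra["confusion"]
        total.TN += c.TN
        total.TD += c.TD
        total.FN += c.FN
        total.FD += c.FD
        count_accs.append(rep.counting_accuracy)
        if rep.iou is not None:
            all_ious.append(rep.iou)
        missed += rep.n_missed
        n_match += rep.n_kernels
    acc, p, r, f1 = confusion_metrics(total)
    return MetricReport(
        acc=acc,
        precision=p,
        recall=r,
        f1=f1,
        counting_accuracy=float(np.mean(count_accs)) if count_accs else None,
        iou=float(np.mean(all_ious)) if all_ious else None,
        dice=None,
        n_kernels=total.total,
        n_missed=missed,
        extra={"confusion": total, "per_scene_counting": count_accs},
    )


def ablation_configs(base: PipelineConfig | None = None) -> dict[str, PipelineConfig]:
    """The four ablation variants sharing every other parameter."""
    base = base or PipelineConfig()
    return {v: replace(base, variant=v) for v in VARIANTS}
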