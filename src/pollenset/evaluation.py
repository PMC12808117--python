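"""Containment-aware COCO-style detection metrics.

Average precision (101-point interpolated area under the precision-recall
envelope) and average recall (recall under a per-image detection cap) are
computed at single IoU thresholds and averaged over the 0.50:0.95 range, the
de facto protocol behind "AP(0.50:0.95)" reporting.  Two wrinkles specific to
tiled slide evaluation are included:

* the containment rule — ground-truth grains with less than a minimum
  fraction (default 80%) of their bounding box inside any single tile are
  excluded, so detectors running on non-overlapping tiles are not penalized
  for boundary-truncated grains they could never see whole;
* class-agnostic matching for confusion matrices, so cross-class confusions
  between morphologically similar taxa are observable off-diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dataset import AnnotationRecord
from .slides import TileRect, containment_fraction, iou

__all__ = [
    "EvalConfig",
    "MatchResult",
    "EvalSummary",
    "ConfusionMatrix",
    "filter_gt_by_containment",
    "match_detections",
    "average_precision",
    "average_recall",
    "evaluate",
    "confusion_matrix",
    "fold_mean_stderr",
]

IOU_RANGE = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))
_RECALL_SAMPLES = np.arange(101) / 100.0


@dataclass(frozen=True)
class EvalConfig:
    """Metric protocol parameters (COCO-style defaults)."""

    iou_thresholds: tuple[float, ...] = IOU_RANGE
    report_singles: tuple[float, ...] = (0.50, 0.75)
    max_detections: int = 100
    min_containment: float = 0.8
    class_aware: bool = True

    def __post_init__(self) -> None:
        if any(not (0.0 < t <= 1.0) for t in self.iou_thresholds):
            raise ValueError("iou thresholds must lie in (0, 1]")
        if list(self.iou_thresholds) != sorted(self.iou_thresholds):
            raise ValueError("iou thresholds must be sorted ascending")


@dataclass
class MatchResult:
    """Greedy matching outcome at one IoU threshold.

    ``detections`` are in evaluation order (score descending, lexicographic
    tie-break); ``det_match[i]`` is the matched index into ``gts`` or None
    (a false positive); ``gt_matched[j]`` marks ground truths found.
    """

    detections: list[AnnotationRecord]
    gts: list[AnnotationRecord]
    det_match: list[Optional[int]]
    det_iou: list[float]
    gt_matched: list[bool]


@dataclass
class EvalSummary:
    """AP/AR at the standard reporting points, plus per-class APs."""

    ap: Optional[float]
    ap50: Optional[float]
    ap75: Optional[float]
    ar: Optional[float]
    ar50: Optional[float]
    ar75: Optional[float]
    per_class_ap: dict[str, Optional[float]]
    n_gt: int
    n_det: int

    def to_dict(self) -> dict:
        return {
            "AP(0.50:0.95)": self.ap,
            "AP(0.50)": self.ap50,
            "AP(0.75)": self.ap75,
            "AR(0.50:0.95)": self.ar,
            "AR(0.50)": self.ar50,
            "AR(0.75)": self.ar75,
            "per_class_AP": self.per_class_ap,
            "n_gt": self.n_gt,
            "n_det": self.n_det,
        }


@dataclass
class ConfusionMatrix:
    """Row-normalized class confusion from class-agnostic matching."""

    classes: list[str]
    matrix: np.ndarray
    row_normalized: bool
    support: np.ndarray
    missed: np.ndarray

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "matrix": self.matrix.tolist(),
            "row_normalized": self.row_normalized,
            "support": self.support.tolist(),
            "missed": self.missed.tolist(),
        }


def filter_gt_by_containment(
    gts: Sequence[AnnotationRecord],
    tiles: Sequence[TileRect],
    min_containment: float = 0.8,
) -> list[AnnotationRecord]:
    """Keep ground truths with >= ``min_containment`` of their box in one tile.

    The comparison is inclusive ("at least"), so a grain with exactly the
    minimum fraction inside its best tile is kept.  ``min_containment=0`` is
    the identity.
    """
    if min_containment <= 0.0:
        return list(gts)
    kept = []
    for gt in gts:
        best = max(
            (containment_fraction(gt.box, t) for t in tiles), default=0.0
        )
        if best >= min_containment:
            kept.append(gt)
    return kept


def _det_order(records: Sequence[AnnotationRecord]) -> list[AnnotationRecord]:
    return sorted(
        records,
        key=lambda r: (-r.score, r.slide_id, r.box.x_min, r.box.y_min,
                       r.box.x_max, r.box.y_max),
    )


def _gt_order(records: Sequence[AnnotationRecord]) -> list[AnnotationRecord]:
    return sorted(
        records,
        key=lambda r: (r.slide_id, r.box.x_min, r.box.y_min, r.box.x_max,
                       r.box.y_max, r.species),
    )


def match_detections(
    dets: Sequence[AnnotationRecord],
    gts: Sequence[AnnotationRecord],
    iou_threshold: float,
    class_aware: bool = True,
) -> MatchResult:
    """Greedily match detections to ground truths at one IoU threshold.

    Detections are visited in descending score; each claims the unmatched
    ground truth on its own slide (and of its own class when ``class_aware``)
    with the highest IoU >= threshold.  Each ground truth matches at most one
    detection.
    """
    dets = _det_order(dets)
    gts = _gt_order(gts)
    gt_matched = [False] * len(gts)
    det_match: list[Optional[int]] = []
    det_iou: list[float] = []
    for d in dets:
        best_j, best_iou = None, 0.0
        for j, g in enumerate(gts):
            if gt_matched[j] or g.slide_id != d.slide_id:
                continue
            if class_aware and g.species != d.species:
                continue
            v = iou(d.box, g.box)
            if v >= iou_threshold and v > best_iou:
                best_j, best_iou = j, v
        if best_j is not None:
            gt_matched[best_j] = True
            det_match.append(best_j)
            det_iou.append(best_iou)
        else:
            det_match.append(None)
            det_iou.append(0.0)
    return MatchResult(dets, gts, det_match, det_iou, gt_matched)


def average_precision(
    dets: Sequence[AnnotationRecord],
    gts: Sequence[AnnotationRecord],
    iou_threshold: float,
    class_aware: bool = True,
) -> Optional[float]:
    """101-point interpolated average precision at one IoU threshold.

    Returns 0.0 when there are detections but no ground truth, and None
    (undefined, excluded from means) when both are empty.
    """
    if len(gts) == 0:
        return None if len(dets) == 0 else 0.0
    if len(dets) == 0:
        return 0.0
    m = match_detections(dets, gts, iou_threshold, class_aware)
    tp = np.array([j is not None for j in m.det_match], dtype=np.float64)
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    recall = cum_tp / len(gts)
    precision = cum_tp / (cum_tp + cum_fp)
    # precision envelope sampled at 101 recall points
    samples = np.zeros_like(_RECALL_SAMPLES)
    for i, r in enumerate(_RECALL_SAMPLES):
        mask = recall >= r - 1e-12
        samples[i] = precision[mask].max() if mask.any() else 0.0
    return float(samples.mean())


def _cap_per_image(
    dets: Sequence[AnnotationRecord], max_detections: int
) -> list[AnnotationRecord]:
    capped: list[AnnotationRecord] = []
    counts: dict[str, int] = {}
    for d in _det_order(dets):
        if counts.get(d.slide_id, 0) < max_detections:
            capped.append(d)
            counts[d.slide_id] = counts.get(d.slide_id, 0) + 1
    return capped


def average_recall(
    dets: Sequence[AnnotationRecord],
    gts: Sequence[AnnotationRecord],
    iou_thresholds: float | Sequence[float],
    max_detections: int = 100,
    class_aware: bool = True,
) -> Optional[float]:
    """Recall of the top-``max_detections`` detections per image.

    For a threshold range, the mean of per-threshold recalls.  None when
    there is no ground truth.
    """
    if len(gts) == 0:
        return None
    if np.isscalar(iou_thresholds):
        iou_thresholds = [float(iou_thresholds)]
    capped = _cap_per_image(dets, max_detections)
    recalls = []
    for t in iou_thresholds:
        m = match_detections(capped, gts, t, class_aware)
        recalls.append(sum(m.gt_matched) / len(gts))
    return float(np.mean(recalls))


def _classes_with_gt(records: Sequence[AnnotationRecord]) -> list[str]:
    return sorted({r.species for r in records})


def _macro(values: Sequence[Optional[float]]) -> Optional[float]:
    present = [v for v in values if v is not None]
    return float(np.mean(present)) if present else None


def evaluate(
    dets: Sequence[AnnotationRecord],
    gts: Sequence[AnnotationRecord],
    config: EvalConfig = EvalConfig(),
) -> EvalSummary:
    """Full metric suite for one evaluation fold.

    When ``class_aware``, AP/AR are macro means over classes with at least
    one ground truth (absent taxa are excluded rather than scored zero);
    otherwise all boxes form one class-agnostic pool.
    """
    if config.class_aware:
        classes = _classes_with_gt(gts)
        groups = [
            (
                [d for d in dets if d.species == c],
                [g for g in gts if g.species == c],
            )
            for c in classes
        ]
    else:
        classes = ["all"]
        groups = [(list(dets), list(gts))]

    def ap_at(thresholds) -> Optional[float]:
        per_class = []
        for cd, cg in groups:
            vals = [average_precision(cd, cg, t, config.class_aware) for t in thresholds]
            per_class.append(_macro(vals))
        return _macro(per_class)

    def ar_at(thresholds) -> Optional[float]:
        per_class = [
            average_recall(cd, cg, thresholds, config.max_detections, config.class_aware)
            for cd, cg in groups
        ]
        return _macro(per_class)

    per_class_ap = {
        c: _macro(
            [average_precision(cd, cg, t, config.class_aware)
             for t in config.iou_thresholds]
        )
        for c, (cd, cg) in zip(classes, groups)
    }
    return EvalSummary(
        ap=ap_at(config.iou_thresholds),
        ap50=ap_at([0.50]),
        ap75=ap_at([0.75]),
        ar=ar_at(config.iou_thresholds),
        ar50=ar_at([0.50]),
        ar75=ar_at([0.75]),
        per_class_ap=per_class_ap,
        n_gt=len(gts),
        n_det=len(dets),
    )


def confusion_matrix(
    dets: Sequence[AnnotationRecord],
    gts: Sequence[AnnotationRecord],
    iou_threshold: float = 0.5,
    normalize: bool = True,
) -> ConfusionMatrix:
    """Row-normalized confusion matrix from class-agnostic matching.

    Matching ignores labels (otherwise off-diagonal confusions could never
    appear); each matched pair increments cell [gt class, detected class].
    Unmatched ground truths are tallied in a separate ``missed`` vector, not
    in the normalized rows.  Zero-support rows are left as zeros.
    """
    classes = sorted({r.species for r in gts} | {r.species for r in dets})
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.float64)
    missed = np.zeros(len(classes), dtype=np.int64)
    m = match_detections(dets, gts, iou_threshold, class_aware=False)
    for i, j in enumerate(m.det_match):
        if j is not None:
            counts[index[m.gts[j].species], index[m.detections[i].species]] += 1
    for j, matched in enumerate(m.gt_matched):
        if not matched:
            missed[index[m.gts[j].species]] += 1
    support = counts.sum(axis=1)
    matrix = counts
    if normalize:
        matrix = np.divide(
            counts,
            support[:, None],
            out=np.zeros_like(counts),
            where=support[:, None] > 0,
        )
    return ConfusionMatrix(
        classes=classes,
        matrix=matrix,
        row_normalized=normalize,
        support=support.astype(np.int64),
        missed=missed,
    )


def fold_mean_stderr(values: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error over evaluation folds (reporting helper)."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("no fold values")
    if arr.size == 1:
        return float(arr[0]), 0.0
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(arr.size))
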