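"""Detection scoring: IoU and 11-point interpolated average precision.

AP per class follows the classic Pascal VOC protocol: detections are
ranked by descending confidence; each detection greedily claims the
highest-IoU not-yet-claimed ground-truth box in its image, a true
positive if that IoU reaches the threshold (0.5 for mAP@50) and a false
positive otherwise.  Precision is interpolated at the eleven recall
levels {0, 0.1, ..., 1} as the maximum precision attained at any recall
at least that large, and AP is their mean.  mAP is the unweighted mean
over classes that have at least one ground-truth box.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core import AnnotationSet, Box, ValidationError, box_iou

iou = box_iou

RECALL_LEVELS = np.linspace(0.0, 1.0, 11)


def _rank(detections: Sequence[tuple[str, Box]]) -> list[tuple[str, Box]]:
    """Descending score, ties broken by input order (stable sort)."""
    for _, box in detections:
        if box.score is None:
            raise ValidationError("detections must carry scores")
    return sorted(detections, key=lambda d: -d[1].score)


def _tp_flags(ranked: Sequence[tuple[str, Box]],
              truths: Sequence[tuple[str, Box]],
              iou_threshold: float) -> np.ndarray:
    """Greedy one-to-one matching flags in rank order."""
    unclaimed: dict[str, list[Box]] = {}
    for image_id, box in truths:
        unclaimed.setdefault(image_id, []).append(box)
    flags = np.zeros(len(ranked), dtype=bool)
    for k, (image_id, det) in enumerate(ranked):
        candidates = unclaimed.get(image_id, [])
        best_i, best_iou = -1, 0.0
        for i, t in enumerate(candidates):
            overlap = box_iou(det, t)
            if overlap > best_iou:
                best_i, best_iou = i, overlap
        if best_i >= 0 and best_iou >= iou_threshold:
            flags[k] = True
            del candidates[best_i]
    return flags


def ap_11point(detections: Sequence[tuple[str, Box]],
               truths: Sequence[tuple[str, Box]],
               iou_threshold: float = 0.5) -> Optional[float]:
    """11-point interpolated AP for one class.

    Parameters
    ----------
    detections
        ``(image_id, box)`` pairs with scores, any order.
    truths
        ``(image_id, box)`` ground-truth pairs of the same class.

    Returns None (undefined) when both inputs are empty; 0.0 with a
    warning when there are detections but no ground truth.
    """
    if not truths:
        if not detections:
            return None
        warnings.warn("detections for a class with no ground truth; AP = 0")
        return 0.0
    if not detections:
        return 0.0
    ranked = _rank(detections)
    flags = _tp_flags(ranked, truths, iou_threshold)
    tp = np.cumsum(flags)
    fp = np.cumsum(~flags)
    recall = tp / len(truths)
    precision = tp / (tp + fp)
    ap = 0.0
    for r in RECALL_LEVELS:
        reachable = precision[recall >= r]
        ap += float(reachable.max()) if reachable.size else 0.0
    return ap / 11.0


@dataclass
class EvalReport:
    """Per-class AP, their mean, and operating-point TP/FP/FN counts."""

    per_class_ap: dict[str, Optional[float]]
    map50: float
    counts: dict[str, dict[str, int]]
    iou_threshold: float = 0.5

    def to_dict(self) -> dict:
        return {
            "iou_threshold": self.iou_threshold,
            "per_class_ap": self.per_class_ap,
            "map": self.map50,
            "counts": self.counts,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def evaluate(detections: AnnotationSet, truths: AnnotationSet,
             iou_threshold: float = 0.5) -> EvalReport:
    """Score a detection set against ground truth, class by class.

    TP/FP counts are taken over all supplied detections (apply a score
    filter beforehand to evaluate at an operating point); FN is the
    number of ground-truth boxes left unmatched.
    """
    classes = sorted(truths.classes | detections.classes)
    per_class_ap: dict[str, Optional[float]] = {}
    counts: dict[str, dict[str, int]] = {}
    defined: list[float] = []
    for cls in classes:
        dets = [(r.image_id, b) for r in detections for b in r.boxes
                if b.label == cls]
        gts = [(r.image_id, b) for r in truths for b in r.boxes
               if b.label == cls]
        ap = ap_11point(dets, gts, iou_threshold)
        per_class_ap[cls] = ap
        if gts:
            defined.append(ap)
        tp = int(_tp_flags(_rank(dets), gts, iou_threshold).sum()) if dets else 0
        counts[cls] = {"tp": tp, "fp": len(dets) - tp, "fn": len(gts) - tp}
    if not defined:
        raise ValidationError("ground truth contains no boxes of any class")
    return EvalReport(
        per_class_ap=per_class_ap,
        map50=float(np.mean(defined)),
        counts=counts,
        iou_threshold=iou_threshold,
    )
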