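"""Pseudo-label curation: score filtering, overlap resolution, control classes.

Model-generated pseudo-labels accumulate redundant and spurious boxes
across self-training rounds.  Three rules curate them:

1. discard detections scoring below a confidence threshold (0.5);
2. among boxes overlapping at IoU >= 0.3, keep the higher-scoring one
   when their categories differ and the larger one when they agree;
3. strip *control* classes (background / unknown / healthy), auxiliary
   categories added only to absorb false-positive-prone regions.

The overlap rule is applied as a single greedy sweep in descending score
order (ties: larger area, then input order), which makes the outcome
independent of input ordering and the whole pipeline idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import AnnotationSet, Box, ImageRecord, ValidationError, box_iou

DEFAULT_CONTROL_LABELS = frozenset({"background", "unknown", "healthy"})


@dataclass(frozen=True)
class PostprocessConfig:
    score_threshold: float = 0.5
    overlap_iou: float = 0.3
    control_labels: frozenset[str] = DEFAULT_CONTROL_LABELS

    def __post_init__(self) -> None:
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValidationError("score_threshold outside [0, 1]")
        if not 0.0 <= self.overlap_iou <= 1.0:
            raise ValidationError("overlap_iou outside [0, 1]")


def filter_by_score(record: ImageRecord, threshold: float) -> ImageRecord:
    """Keep boxes with score >= threshold (inclusive); order preserved."""
    for box in record.boxes:
        if box.score is None:
            raise ValidationError(
                f"{record.image_id}: box without score cannot be filtered"
            )
    return record.with_boxes([b for b in record.boxes if b.score >= threshold])


def resolve_overlaps(record: ImageRecord, config: PostprocessConfig
                     ) -> ImageRecord:
    """Resolve pairs of overlapping boxes at the configured IoU threshold.

    Boxes are swept greedily in descending score order.  A candidate that
    overlaps any accepted box of a *different* category is discarded (the
    accepted box was scored at least as high).  Against accepted boxes of
    the *same* category the size rule wins: the larger-area box of the
    two is kept, so a bigger low-score box evicts a smaller accepted one.
    The output carries no remaining pair at or above the threshold.
    """
    for box in record.boxes:
        if box.score is None:
            raise ValidationError(
                f"{record.image_id}: box without score in overlap resolution"
            )
    order = sorted(range(len(record.boxes)),
                   key=lambda i: (-record.boxes[i].score,
                                  -record.boxes[i].area, i))
    accepted: list[Box] = []
    for i in order:
        cand = record.boxes[i]
        evict: list[int] = []
        keep = True
        for j, acc in enumerate(accepted):
            if box_iou(cand, acc) < config.overlap_iou:
                continue
            if acc.label != cand.label:
                keep = False
                break
            if cand.area > acc.area:
                evict.append(j)
            else:
                keep = False
                break
        if keep:
            for j in reversed(evict):
                del accepted[j]
            accepted.append(cand)
    accepted.sort(key=lambda b: (-b.score, -b.area))
    return record.with_boxes(accepted)


def strip_control_classes(record: ImageRecord,
                          control_labels: frozenset[str] | set[str]
                          ) -> ImageRecord:
    """Remove boxes whose label is a control class."""
    return record.with_boxes(
        [b for b in record.boxes if b.label not in control_labels]
    )


def postprocess(annotations: AnnotationSet,
                config: PostprocessConfig = PostprocessConfig()
                ) -> AnnotationSet:
    """Apply score filter, overlap resolution and control stripping per image."""
    out = AnnotationSet()
    for record in annotations:
        r = filter_by_score(record, config.score_threshold)
        r = resolve_overlaps(r, config)
        r = strip_control_classes(r, config.control_labels)
        out.add(r)
    return out
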