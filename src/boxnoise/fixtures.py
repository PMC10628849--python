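"""Synthetic annotation and detection sets with controllable structure.

No real imagery or label download is needed anywhere in the package: the
generators here produce annotation sets whose geometry has the
statistical structure the analyses assume — square images, a log-uniform
box-side law (so the small / middle / large size classes are all
populated), uniform placement, a Poisson box count per image, and either
a multi-class label set (disease-survey-like) or a single class
(wheat-head-like).  Detection sets derive from a truth set by dropping
boxes (false negatives), perturbing survivors with size-proportional
localization noise, scoring them, and injecting spurious scored boxes
(false positives).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .core import AnnotationSet, Box, ImageRecord, ValidationError
from .synthesis import NoiseModel, perturb_box

DEFAULT_CLASSES = (
    "blossom_end_rot",
    "gray_mold",
    "powdery_mildew",
    "spider_mite",
    "spotting_disease",
)


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of the synthetic annotation generator.

    ``boxes_per_image`` is a Poisson mean; draws are clipped to at least
    one box per image.  ``size_range`` is the log-uniform support of the
    box side length in pixels.
    """

    n_images: int = 100
    image_size: float = 640.0
    classes: Sequence[str] = DEFAULT_CLASSES
    boxes_per_image: float = 3.0
    size_range: tuple[float, float] = (16.0, 480.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 0:
            raise ValidationError("n_images must be non-negative")
        lo, hi = self.size_range
        if not (0 < lo <= hi <= self.image_size):
            raise ValidationError(
                f"size range {self.size_range} outside (0, {self.image_size}]"
            )
        if not self.classes:
            raise ValidationError("at least one class is required")


def generate_annotation_set(config: FixtureConfig) -> AnnotationSet:
    """Generate a deterministic synthetic clean annotation set."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.size_range
    size = config.image_size
    annotations = AnnotationSet()
    for i in range(config.n_images):
        n_boxes = max(1, int(rng.poisson(config.boxes_per_image)))
        boxes = []
        for _ in range(n_boxes):
            w = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            h = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            left = float(rng.uniform(0.0, size - w))
            top = float(rng.uniform(0.0, size - h))
            label = config.classes[int(rng.integers(len(config.classes)))]
            boxes.append(Box(left=left, top=top, right=left + w,
                             bottom=top + h, label=label))
        annotations.add(ImageRecord(
            image_id=f"img_{i:05d}", width=size, height=size, boxes=boxes))
    return annotations


def _default_tp_score(rng: np.random.Generator) -> float:
    return float(rng.uniform(0.5, 1.0))


def _default_fp_score(rng: np.random.Generator) -> float:
    return float(rng.uniform(0.0, 0.7))


def generate_detections(truths: AnnotationSet,
                        loc_gamma: float = 0.1,
                        score_law: Optional[Callable[[np.random.Generator], float]] = None,
                        fp_rate: float = 0.0,
                        fn_rate: float = 0.0,
                        seed: int = 0,
                        fp_classes: Optional[Sequence[str]] = None,
                        fp_size_range: tuple[float, float] = (16.0, 200.0),
                        ) -> AnnotationSet:
    """Derive a scored detection set from a truth set.

    Each truth box is dropped with probability ``fn_rate``; survivors are
    perturbed at ``loc_gamma`` and scored by ``score_law`` (default:
    uniform on [0.5, 1], so the conventional 0.5 confidence cut keeps
    them).  Spurious boxes are added per image with a Poisson(``fp_rate``)
    count, scored uniform on [0, 0.7] and labelled from ``fp_classes``
    (default: the classes of ``truths``).
    """
    if not 0.0 <= fp_rate or not 0.0 <= fn_rate <= 1.0:
        raise ValidationError("fp_rate must be >= 0 and fn_rate in [0, 1]")
    rng = np.random.default_rng(seed)
    score_law = score_law or _default_tp_score
    labels = tuple(fp_classes) if fp_classes is not None else tuple(sorted(truths.classes))
    model = NoiseModel(gamma=loc_gamma, seed=seed)
    detections = AnnotationSet()
    for record in truths:
        boxes: list[Box] = []
        for box in record.boxes:
            if rng.random() < fn_rate:
                continue
            noisy = perturb_box(box, model, record.width, record.height, rng)
            boxes.append(Box(noisy.left, noisy.top, noisy.right, noisy.bottom,
                             label=box.label, score=score_law(rng)))
        for _ in range(int(rng.poisson(fp_rate))):
            lo, hi = fp_size_range
            w = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            h = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            left = float(rng.uniform(0.0, record.width - w))
            top = float(rng.uniform(0.0, record.height - h))
            boxes.append(Box(left, top, left + w, top + h,
                             label=labels[int(rng.integers(len(labels)))],
                             score=_default_fp_score(rng)))
        detections.add(record.with_boxes(boxes))
    return detections
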