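"""Core geometric types for annotation sets.

Coordinates are continuous and 0-based, with box edges treated as real
lines, so ``width = right - left`` and ``height = bottom - top`` are exact.
A :class:`Box` is one labelled axis-aligned rectangle with an optional
confidence score; an :class:`ImageRecord` groups the boxes of one image
together with its pixel dimensions; an :class:`AnnotationSet` is a whole
label set keyed by image id.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional


class ValidationError(ValueError):
    """Raised when a box, record or set violates its invariants."""


@dataclass(frozen=True)
class Box:
    """One labelled rectangle.

    Parameters
    ----------
    left, top, right, bottom
        Boundary coordinates in pixels; ``left < right`` and
        ``top < bottom`` are enforced strictly (zero-area boxes are
        invalid).
    label
        Category name.
    score
        Optional confidence in [0, 1]; absent for ground truth.
    """

    left: float
    top: float
    right: float
    bottom: float
    label: str
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.left < self.right and self.top < self.bottom):
            raise ValidationError(
                f"degenerate box: ({self.left}, {self.top}, "
                f"{self.right}, {self.bottom})"
            )
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValidationError(f"score {self.score} outside [0, 1]")

    @property
    def width(self) -> float:
        return self.right - self.left

    @property
    def height(self) -> float:
        return self.bottom - self.top

    @property
    def area(self) -> float:
        return self.width * self.height


def box_iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint."""
    iw = min(a.right, b.right) - max(a.left, b.left)
    ih = min(a.bottom, b.bottom) - max(a.top, b.top)
    if iw <= 0.0 or ih <= 0.0:
        return 0.0
    inter = iw * ih
    return inter / (a.area + b.area - inter)


def clip_box(box: Box, width: float, height: float) -> Box:
    """Clamp a box into the image rectangle [0, W] x [0, H].

    Raises :class:`ValidationError` if clamping collapses the box to zero
    width or height; callers that perturb boxes must resample instead of
    accepting a degenerate result.
    """
    if width <= 0 or height <= 0:
        raise ValidationError("image dimensions must be positive")
    left = min(max(box.left, 0.0), width)
    right = min(max(box.right, 0.0), width)
    top = min(max(box.top, 0.0), height)
    bottom = min(max(box.bottom, 0.0), height)
    if left >= right or top >= bottom:
        raise ValidationError(
            f"clipping to {width}x{height} collapsed box "
            f"({box.left}, {box.top}, {box.right}, {box.bottom})"
        )
    if (left, top, right, bottom) == (box.left, box.top, box.right, box.bottom):
        return box
    return replace(box, left=left, top=top, right=right, bottom=bottom)


@dataclass
class ImageRecord:
    """One image's identity, dimensions and boxes."""

    image_id: str
    width: float
    height: float
    boxes: list[Box] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValidationError(
                f"{self.image_id}: non-positive image dimensions "
                f"{self.width}x{self.height}"
            )
        for box in self.boxes:
            self._check_bounds(box)

    def _check_bounds(self, box: Box) -> None:
        if box.left < 0 or box.top < 0 or box.right > self.width or box.bottom > self.height:
            raise ValidationError(
                f"{self.image_id}: box ({box.left}, {box.top}, {box.right}, "
                f"{box.bottom}) outside image {self.width}x{self.height}"
            )

    def with_boxes(self, boxes: list[Box]) -> "ImageRecord":
        return ImageRecord(self.image_id, self.width, self.height, list(boxes))


@dataclass
class AnnotationSet:
    """A label set: mapping of image id to :class:`ImageRecord`."""

    records: dict[str, ImageRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for image_id, record in self.records.items():
            if record.image_id != image_id:
                raise ValidationError(
                    f"key {image_id!r} does not match record id "
                    f"{record.image_id!r}"
                )

    @property
    def classes(self) -> set[str]:
        return {b.label for r in self.records.values() for b in r.boxes}

    @property
    def n_images(self) -> int:
        return len(self.records)

    @property
    def n_boxes(self) -> int:
        return sum(len(r.boxes) for r in self.records.values())

    def __iter__(self) -> Iterator[ImageRecord]:
        """Iterate records in sorted image-id order (deterministic)."""
        for image_id in sorted(self.records):
            yield self.records[image_id]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, image_id: str) -> ImageRecord:
        return self.records[image_id]

    def add(self, record: ImageRecord) -> None:
        if record.image_id in self.records:
            raise ValidationError(f"duplicate image id {record.image_id!r}")
        self.records[record.image_id] = record


def check_aligned(a: AnnotationSet, b: AnnotationSet) -> None:
    """Verify two sets are structurally aligned.

    Alignment means the same image ids, the same per-image box counts and
    index-wise identical labels, so that boxes correspond one-to-one by
    (image id, box index).
    """
    if set(a.records) != set(b.records):
        only_a = sorted(set(a.records) - set(b.records))[:3]
        only_b = sorted(set(b.records) - set(a.records))[:3]
        raise ValidationError(
            f"image ids differ (e.g. only in first: {only_a}, "
            f"only in second: {only_b})"
        )
    for image_id in sorted(a.records):
        ra, rb = a.records[image_id], b.records[image_id]
        if len(ra.boxes) != len(rb.boxes):
            raise ValidationError(
                f"{image_id}: box counts differ "
                f"({len(ra.boxes)} vs {len(rb.boxes)})"
            )
        for i, (ba, bb) in enumerate(zip(ra.boxes, rb.boxes)):
            if ba.label != bb.label:
                raise ValidationError(
                    f"{image_id}: label mismatch at box {i} "
                    f"({ba.label!r} vs {bb.label!r})"
                )
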