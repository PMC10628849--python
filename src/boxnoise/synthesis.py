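"""Size-proportional Gaussian boundary noise for clean annotation sets.

Each boundary of each box receives an independent perturbation
``Delta ~ N(0, (gamma * S)^2)`` with ``S`` the box width for the
left/right boundaries and the height for top/bottom, so the relative
error ``Delta / S`` is N(0, gamma^2) regardless of box size.  The noisy
boundary is ``clean - Delta``, which makes the measured error
``clean - noisy`` equal to the drawn ``Delta`` (before clipping at the
image border).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import AnnotationSet, Box, ImageRecord, ValidationError


@dataclass(frozen=True)
class NoiseModel:
    """Generative noise law: relative boundary errors are N(0, gamma^2).

    ``max_resample`` bounds the redraw attempts when a perturbation
    inverts or collapses a box; ``min_side`` is the smallest side length
    (pixels) a perturbed box may have.
    """

    gamma: float
    seed: int = 0
    max_resample: int = 25
    min_side: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValidationError("gamma must be non-negative")
        if self.max_resample < 1:
            raise ValidationError("max_resample must be at least 1")


def _fallback(box: Box, width: float, height: float, min_side: float) -> Box:
    """The clean box, expanded to min_side if needed and clamped inside."""
    left, right = box.left, box.right
    if right - left < min_side:
        mid = 0.5 * (left + right)
        left, right = mid - min_side / 2, mid + min_side / 2
    top, bottom = box.top, box.bottom
    if bottom - top < min_side:
        mid = 0.5 * (top + bottom)
        top, bottom = mid - min_side / 2, mid + min_side / 2
    left = min(max(left, 0.0), width - min_side)
    top = min(max(top, 0.0), height - min_side)
    right = max(min(right, width), left + min_side)
    bottom = max(min(bottom, height), top + min_side)
    return replace(box, left=left, top=top, right=right, bottom=bottom)


def perturb_box(box: Box, model: NoiseModel, width: float, height: float,
                rng: np.random.Generator) -> Box:
    """Perturb the four boundaries of one box; never returns a degenerate box.

    Draws are redrawn up to ``model.max_resample`` times if clipping to
    the image leaves a side below ``model.min_side``; after that the
    clean box itself (clamped to validity) is returned.  Label and score
    pass through unchanged.
    """
    sd_w = model.gamma * box.width
    sd_h = model.gamma * box.height
    for _ in range(model.max_resample):
        d_left, d_right = rng.normal(0.0, sd_w, size=2)
        d_top, d_bottom = rng.normal(0.0, sd_h, size=2)
        left = min(max(box.left - d_left, 0.0), width)
        right = min(max(box.right - d_right, 0.0), width)
        top = min(max(box.top - d_top, 0.0), height)
        bottom = min(max(box.bottom - d_bottom, 0.0), height)
        if right - left >= model.min_side and bottom - top >= model.min_side:
            return replace(box, left=left, top=top, right=right, bottom=bottom)
    return _fallback(box, width, height, model.min_side)


def synthesize(clean: AnnotationSet, model: NoiseModel) -> AnnotationSet:
    """Apply the noise model to every box of every record.

    One RNG stream seeded from ``model.seed`` is consumed in a fixed
    traversal order (sorted image id, then box index), so identical
    inputs give identical outputs.  The output has the same image ids,
    per-image box counts, labels and scores as the input.
    """
    rng = np.random.default_rng(model.seed)
    noisy = AnnotationSet()
    for record in clean:
        boxes = [perturb_box(b, model, record.width, record.height, rng)
                 for b in record.boxes]
        noisy.add(ImageRecord(record.image_id, record.width, record.height, boxes))
    return noisy
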