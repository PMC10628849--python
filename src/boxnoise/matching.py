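"""Matching of clean to noisy boxes and localization-noise diagnostics.

The noise level of an annotation set is summarised by the root mean square
relative boundary error

    gamma = sqrt( (1/n) * sum_i (Delta_i / S_i)^2 )

where ``Delta_i`` is the signed difference between a boundary of a clean
box and the corresponding boundary of its matched noisy box
(``Delta = clean - noisy``), and ``S_i`` is the clean box width for the
left/right boundaries or its height for top/bottom.  The absolute-error
dispersion ``sigma = sqrt(mean(Delta^2))`` scales with box size: binning
the errors by box size and fitting a through-origin line to the per-bin
sigma recovers gamma as the slope, which is what licenses synthesizing
noise as ``Delta ~ N(0, (gamma * S)^2)`` independently on each boundary.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .core import AnnotationSet, Box, ImageRecord, ValidationError, box_iou

logger = logging.getLogger(__name__)

BOUNDARIES = ("left", "top", "right", "bottom")
Boundary = Literal["left", "top", "right", "bottom"]
SizeClass = Literal["small", "middle", "large"]

#: size-class thresholds on the box-side to image-side ratio:
#: (0, 0.1] small, (0.1, 0.3] middle, (0.3, 1] large
SMALL_MAX = 0.1
LARGE_MIN = 0.3


def size_class(side: float, image_side: float) -> SizeClass:
    """Classify a box side length relative to its image dimension."""
    if not 0 < side <= image_side:
        raise ValidationError(
            f"box side {side} outside (0, image side {image_side}]"
        )
    ratio = side / image_side
    if ratio <= SMALL_MAX:
        return "small"
    if ratio > LARGE_MIN:
        return "large"
    return "middle"


@dataclass(frozen=True)
class BoundaryError:
    """Signed localization error of one box boundary.

    ``delta`` is the absolute (pixel) error clean - noisy; ``scale`` is
    the clean box width (left/right) or height (top/bottom);
    ``image_extent`` the matching image dimension, kept so errors can be
    rescaled to a common reference image size and size-classed.
    """

    boundary: Boundary
    delta: float
    scale: float
    image_extent: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValidationError(f"non-positive scale {self.scale}")

    @property
    def relative(self) -> float:
        return self.delta / self.scale

    @property
    def size_class(self) -> SizeClass:
        return size_class(self.scale, self.image_extent)


@dataclass(frozen=True)
class MatchPair:
    """A clean box, its matched noisy box, their IoU and the four errors."""

    image_id: str
    clean: Box
    noisy: Box
    iou: float
    errors: tuple[BoundaryError, BoundaryError, BoundaryError, BoundaryError]

    def __post_init__(self) -> None:
        if self.clean.label != self.noisy.label:
            raise ValidationError("matched boxes must share a label")
        if not self.iou > 0:
            raise ValidationError("matched pair requires positive IoU")


def boundary_errors(clean: Box, noisy: Box, width: float, height: float
                    ) -> tuple[BoundaryError, ...]:
    """Four per-boundary errors, Delta = clean - noisy, scaled by w or h."""
    return (
        BoundaryError("left", clean.left - noisy.left, clean.width, width),
        BoundaryError("top", clean.top - noisy.top, clean.height, height),
        BoundaryError("right", clean.right - noisy.right, clean.width, width),
        BoundaryError("bottom", clean.bottom - noisy.bottom, clean.height, height),
    )


def match_boxes(clean: ImageRecord, noisy: ImageRecord) -> list[MatchPair]:
    """Match each clean box to its maximum-IoU same-label noisy box.

    Every clean box is considered independently, so a noisy box may be
    matched by several clean boxes.  Clean boxes with no positive-IoU
    same-label candidate are left unmatched (they are simply absent from
    the returned list; callers count them as ``n_clean - n_pairs``).
    """
    if clean.image_id != noisy.image_id:
        raise ValidationError(
            f"records refer to different images "
            f"({clean.image_id!r} vs {noisy.image_id!r})"
        )
    if (clean.width, clean.height) != (noisy.width, noisy.height):
        raise ValidationError(
            f"{clean.image_id}: image dimensions differ "
            f"({clean.width}x{clean.height} vs {noisy.width}x{noisy.height})"
        )
    pairs: list[MatchPair] = []
    for cbox in clean.boxes:
        best: Optional[Box] = None
        best_iou = 0.0
        for nbox in noisy.boxes:
            if nbox.label != cbox.label:
                continue
            overlap = box_iou(cbox, nbox)
            if overlap > best_iou:
                best, best_iou = nbox, overlap
        if best is not None:
            pairs.append(MatchPair(
                image_id=clean.image_id, clean=cbox, noisy=best, iou=best_iou,
                errors=boundary_errors(cbox, best, clean.width, clean.height),
            ))
    return pairs


def gamma(errors: Sequence[BoundaryError]) -> float:
    """Root mean square relative error over a collection of boundary errors."""
    if len(errors) == 0:
        raise ValidationError("gamma of an empty error collection is undefined")
    rel = np.array([e.relative for e in errors])
    return float(np.sqrt(np.mean(rel ** 2)))


def sigma(errors: Sequence[BoundaryError]) -> float:
    """Root mean square absolute error (pixels)."""
    if len(errors) == 0:
        raise ValidationError("sigma of an empty error collection is undefined")
    delta = np.array([e.delta for e in errors])
    return float(np.sqrt(np.mean(delta ** 2)))


def binned_sigma(errors: Sequence[BoundaryError],
                 bin_width: float = 64.0,
                 rescale_to: float = 640.0,
                 min_count: int = 10) -> list[tuple[float, float]]:
    """Local sigma of the absolute errors binned by box size.

    Sizes and errors are first rescaled to a square reference image of
    side ``rescale_to`` (each error by ``rescale_to / image_extent``), so
    sets with heterogeneous image sizes share one size axis.  Errors are
    grouped into ``[0, bin_width), [bin_width, 2*bin_width), ...`` by the
    rescaled size; bins holding fewer than ``min_count`` errors are
    dropped.  Returns ``(mean size, local sigma)`` points ordered by size.
    """
    if len(errors) == 0:
        raise ValidationError("binned_sigma of an empty collection is undefined")
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    factor = np.array([rescale_to / e.image_extent for e in errors])
    sizes = np.array([e.scale for e in errors]) * factor
    deltas = np.array([e.delta for e in errors]) * factor
    bins = np.floor(sizes / bin_width).astype(int)
    points: list[tuple[float, float]] = []
    for b in np.unique(bins):
        mask = bins == b
        if mask.sum() < min_count:
            continue
        points.append((float(sizes[mask].mean()),
                       float(np.sqrt(np.mean(deltas[mask] ** 2)))))
    return points


def fit_sigma_slope(points: Sequence[tuple[float, float]]) -> float:
    """Least-squares slope of a through-origin line sigma = slope * size."""
    if len(points) < 2:
        raise ValidationError("need at least two (size, sigma) points")
    s = np.array([p[0] for p in points])
    y = np.array([p[1] for p in points])
    return float(np.sum(s * y) / np.sum(s ** 2))


@dataclass
class CorrelationMatrix:
    """4x4 Pearson correlations of the per-boundary relative errors.

    ``values[i, j]`` correlates boundaries ``BOUNDARIES[i]`` and
    ``BOUNDARIES[j]``; entries involving a zero-variance (constant) error
    series are undefined and flagged False in ``defined`` rather than
    propagated as NaN.
    """

    values: np.ndarray
    defined: np.ndarray

    def __getitem__(self, key):
        return self.values[key]

    def to_lists(self) -> dict:
        return {
            "boundaries": list(BOUNDARIES),
            "values": [[None if not d else float(v)
                        for v, d in zip(row, drow)]
                       for row, drow in zip(self.values, self.defined)],
        }


def boundary_correlation(pairs: Sequence[MatchPair]) -> CorrelationMatrix:
    """Pairwise Pearson correlation of the four relative-error series."""
    if len(pairs) < 3:
        raise ValidationError("need at least 3 pairs for correlations")
    series = np.array([[e.relative for e in p.errors] for p in pairs]).T
    stds = series.std(axis=1)
    values = np.eye(4)
    defined = np.ones((4, 4), dtype=bool)
    for i in range(4):
        for j in range(i + 1, 4):
            if stds[i] == 0.0 or stds[j] == 0.0:
                defined[i, j] = defined[j, i] = False
                values[i, j] = values[j, i] = np.nan
            else:
                r = float(np.corrcoef(series[i], series[j])[0, 1])
                values[i, j] = values[j, i] = r
    return CorrelationMatrix(values=values, defined=defined)


@dataclass
class NoiseReport:
    """Full localization-noise diagnostics for a clean/noisy set pair."""

    n_images: int
    n_pairs: int
    n_unmatched_clean: int
    gamma_overall: float
    gamma_per_boundary: dict[str, float]
    mean_relative_per_boundary: dict[str, float]
    sigma_overall: float
    binned_sigma: list[tuple[float, float]]
    sigma_slope: Optional[float]
    correlation: CorrelationMatrix
    size_class_stats: dict[str, dict[str, float]]
    histograms: dict[str, dict] = field(default_factory=dict)

    @property
    def n_errors(self) -> int:
        return 4 * self.n_pairs

    def to_dict(self) -> dict:
        return {
            "n_images": self.n_images,
            "n_pairs": self.n_pairs,
            "n_unmatched_clean": self.n_unmatched_clean,
            "n_errors": self.n_errors,
            "gamma_overall": self.gamma_overall,
            "gamma_per_boundary": self.gamma_per_boundary,
            "mean_relative_per_boundary": self.mean_relative_per_boundary,
            "sigma_overall": self.sigma_overall,
            "binned_sigma": [[s, v] for s, v in self.binned_sigma],
            "sigma_slope": self.sigma_slope,
            "correlation": self.correlation.to_lists(),
            "size_class_stats": self.size_class_stats,
            "histograms": self.histograms,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def noise_report(clean: AnnotationSet, noisy: AnnotationSet,
                 bin_width: float = 64.0,
                 rescale_to: float = 640.0,
                 min_bin_count: int = 10,
                 histogram_bins: int = 40,
                 histogram_range: tuple[float, float] = (-1.0, 1.0)
                 ) -> NoiseReport:
    """Match two versions of a label set and compute all noise diagnostics.

    Images present in only one of the two sets are logged and skipped;
    an empty intersection of image ids is an error.
    """
    shared = sorted(set(clean.records) & set(noisy.records))
    if not shared:
        raise ValidationError("clean and noisy sets share no image ids")
    skipped = (set(clean.records) | set(noisy.records)) - set(shared)
    if skipped:
        logger.info("skipping %d images present in only one set", len(skipped))

    pairs: list[MatchPair] = []
    n_unmatched = 0
    for image_id in shared:
        matched = match_boxes(clean.records[image_id], noisy.records[image_id])
        n_unmatched += len(clean.records[image_id].boxes) - len(matched)
        pairs.extend(matched)
    if not pairs:
        raise ValidationError("no clean box could be matched to a noisy box")

    errors = [e for p in pairs for e in p.errors]
    by_boundary = {b: [e for e in errors if e.boundary == b] for b in BOUNDARIES}

    points = binned_sigma(errors, bin_width=bin_width, rescale_to=rescale_to,
                          min_count=min_bin_count)
    slope = fit_sigma_slope(points) if len(points) >= 2 else None

    size_stats: dict[str, dict[str, float]] = {}
    histograms: dict[str, dict] = {}
    for cls in ("small", "middle", "large"):
        rel = np.array([e.relative for e in errors if e.size_class == cls])
        if rel.size == 0:
            continue
        size_stats[cls] = {
            "n": int(rel.size),
            "mean": float(rel.mean()),
            "std": float(rel.std()),
        }
        counts, edges = np.histogram(rel, bins=histogram_bins,
                                     range=histogram_range)
        histograms[cls] = {"edges": edges.tolist(), "counts": counts.tolist()}

    return NoiseReport(
        n_images=len(shared),
        n_pairs=len(pairs),
        n_unmatched_clean=n_unmatched,
        gamma_overall=gamma(errors),
        gamma_per_boundary={b: gamma(by_boundary[b]) for b in BOUNDARIES},
        mean_relative_per_boundary={
            b: float(np.mean([e.relative for e in by_boundary[b]]))
            for b in BOUNDARIES
        },
        sigma_overall=sigma(errors),
        binned_sigma=points,
        sigma_slope=slope,
        correlation=boundary_correlation(pairs) if len(pairs) >= 3 else
        CorrelationMatrix(values=np.full((4, 4), np.nan),
                          defined=np.zeros((4, 4), dtype=bool)),
        size_class_stats=size_stats,
        histograms=histograms,
    )
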