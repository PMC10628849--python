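import numpy as np
import pytest

from boxnoise import DEFAULT_CLASSES, AnnotationSet, Box, ImageRecord


def edge_safe_set(n_boxes: int, seed: int,
                  side: tuple[float, float] = (32.0, 280.0),
                  image: float = 640.0,
                  margin: float = 0.6) -> AnnotationSet:
    """One-box-per-image clean set with every boundary at least
    ``margin * side`` from the image border, so Gaussian perturbations up
    to gamma ~ margin/3 are essentially never clipped and moment checks
    see the undistorted noise law."""
    rng = np.random.default_rng(seed)
    annotations = AnnotationSet()
    classes = list(DEFAULT_CLASSES)
    lo, hi = side
    for i in range(n_boxes):
        w = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        h = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        left = float(rng.uniform(margin * w, image - w * (1 + margin)))
        top = float(rng.uniform(margin * h, image - h * (1 + margin)))
        annotations.add(ImageRecord(
            f"img_{i:05d}", image, image,
            [Box(left, top, left + w, top + h, classes[i % len(classes)])]))
    return annotations


@pytest.fixture(scope="session")
def edge_safe_clean() -> AnnotationSet:
    return edge_safe_set(5000, seed=42)


@pytest.fixture
def toy_record() -> ImageRecord:
    return ImageRecord("toy", 640, 640, [
        Box(10, 10, 110, 210, "gray_mold"),
        Box(300, 300, 400, 380, "powdery_mildew"),
    ])
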