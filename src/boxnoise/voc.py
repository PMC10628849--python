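"""Pascal VOC XML reading/writing and a JSON dialect for scored detections.

VOC files store 1-based inclusive integer pixel coordinates.  On read they
are converted to the package's continuous 0-based edge convention:

    left = xmin - 1,  top = ymin - 1,  right = xmax,  bottom = ymax

and the inverse (with rounding to the nearest integer) on write, so a
write/read round trip reproduces every boundary within 0.5 px.  VOC has no
confidence field; a ``<score>`` child of ``<object>`` is used so ground
truth and pseudo-label sets share one format.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Union

from lxml import etree

from .core import AnnotationSet, Box, ImageRecord, ValidationError, clip_box

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class VocParseError(ValueError):
    """Malformed VOC XML; the message names the offending file."""


def _parse_file(path: Path, permissive: bool) -> ImageRecord:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise VocParseError(f"{path}: malformed XML ({exc})") from exc
    root = tree.getroot()
    size = root.find("size")
    if size is None or size.find("width") is None or size.find("height") is None:
        raise VocParseError(f"{path}: missing size/width/height")
    width = float(size.findtext("width"))
    height = float(size.findtext("height"))
    boxes: list[Box] = []
    for i, obj in enumerate(root.iter("object")):
        name = obj.findtext("name")
        bnd = obj.find("bndbox")
        if name is None or bnd is None:
            raise VocParseError(f"{path}: object {i} missing name or bndbox")
        try:
            xmin = float(bnd.findtext("xmin"))
            ymin = float(bnd.findtext("ymin"))
            xmax = float(bnd.findtext("xmax"))
            ymax = float(bnd.findtext("ymax"))
        except (TypeError, ValueError) as exc:
            raise VocParseError(f"{path}: object {i} has non-numeric bndbox") from exc
        score_text = obj.findtext("score")
        score = float(score_text) if score_text is not None else None
        if xmax <= xmin or ymax <= ymin:
            msg = (
                f"{path}: object {i} ({name!r}) has inverted or empty bndbox "
                f"xmin={xmin} ymin={ymin} xmax={xmax} ymax={ymax}"
            )
            if permissive:
                logger.warning("skipping invalid object: %s", msg)
                continue
            raise ValidationError(msg)
        box = Box(left=xmin - 1.0, top=ymin - 1.0, right=xmax, bottom=ymax,
                  label=name, score=score)
        boxes.append(clip_box(box, width, height))
    return ImageRecord(image_id=path.stem, width=width, height=height, boxes=boxes)


def read_voc(path: PathLike, permissive: bool = False) -> AnnotationSet:
    """Read a VOC XML file or a directory of them into an AnnotationSet.

    Parameters
    ----------
    path
        A single ``.xml`` file or a directory scanned for ``*.xml``.
    permissive
        If True, invalid objects (inverted boxes) are skipped with a
        warning instead of raising.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation path does not exist: {path}")
    files = [path] if path.is_file() else sorted(path.glob("*.xml"))
    annotations = AnnotationSet()
    for f in files:
        annotations.add(_parse_file(f, permissive))
    return annotations


def write_voc(annotations: AnnotationSet, path: PathLike) -> int:
    """Write one VOC XML file per image record; returns the file count."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    count = 0
    for record in annotations:
        root = etree.Element("annotation")
        etree.SubElement(root, "filename").text = f"{record.image_id}.jpg"
        size = etree.SubElement(root, "size")
        etree.SubElement(size, "width").text = str(int(round(record.width)))
        etree.SubElement(size, "height").text = str(int(round(record.height)))
        etree.SubElement(size, "depth").text = "3"
        for box in record.boxes:
            obj = etree.SubElement(root, "object")
            etree.SubElement(obj, "name").text = box.label
            if box.score is not None:
                etree.SubElement(obj, "score").text = repr(box.score)
            bnd = etree.SubElement(obj, "bndbox")
            etree.SubElement(bnd, "xmin").text = str(int(round(box.left)) + 1)
            etree.SubElement(bnd, "ymin").text = str(int(round(box.top)) + 1)
            etree.SubElement(bnd, "xmax").text = str(int(round(box.right)))
            etree.SubElement(bnd, "ymax").text = str(int(round(box.bottom)))
        tree = etree.ElementTree(root)
        tree.write(str(path / f"{record.image_id}.xml"),
                   pretty_print=True, encoding="utf-8")
        count += 1
    return count


def write_detections_json(annotations: AnnotationSet, path: PathLike) -> None:
    """Serialize a scored set to the JSON detection dialect.

    The payload carries per-image dimensions alongside the flat detection
    list ``{image_id, label, score, left, top, right, bottom}`` so the set
    can be reconstructed without the source images.
    """
    payload = {
        "images": {
            r.image_id: {"width": r.width, "height": r.height}
            for r in annotations
        },
        "detections": [
            {
                "image_id": r.image_id,
                "label": b.label,
                "score": b.score,
                "left": b.left,
                "top": b.top,
                "right": b.right,
                "bottom": b.bottom,
            }
            for r in annotations
            for b in r.boxes
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_detections_json(path: PathLike,
                         default_size: tuple[float, float] = (640.0, 640.0)
                         ) -> AnnotationSet:
    """Read the JSON detection dialect back into an AnnotationSet.

    Accepts either the object form written by
    :func:`write_detections_json` or a bare list of detection dicts, in
    which case every image is assumed to have ``default_size``.
    """
    data = json.loads(Path(path).read_text())
    if isinstance(data, list):
        images: dict[str, dict] = {}
        detections = data
    else:
        images = data.get("images", {})
        detections = data["detections"]
    annotations = AnnotationSet()
    seen: dict[str, list[Box]] = {}
    for d in detections:
        seen.setdefault(d["image_id"], []).append(
            Box(left=d["left"], top=d["top"], right=d["right"],
                bottom=d["bottom"], label=d["label"], score=d.get("score"))
        )
    for image_id in images.keys() | seen.keys():
        meta = images.get(image_id, {})
        annotations.add(ImageRecord(
            image_id=image_id,
            width=meta.get("width", default_size[0]),
            height=meta.get("height", default_size[1]),
            boxes=seen.get(image_id, []),
        ))
    return annotations
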