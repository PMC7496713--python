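"""Domain types and I/O for trap-image annotations and detections.

Annotation classes follow the trap-labelling vocabulary: ``DSM`` (male
*Drosophila suzukii*), ``DSF`` (female) and ``BC`` (bycatch, any other
trapped insect). Boxes are stored 0-based and half-open ``[min, max)``
internally; the Pascal VOC XML files written by LabelImg use 1-based
inclusive pixel coordinates, and that conversion happens only at the I/O
boundary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

CLASSES = ("DSM", "DSF", "BC")
FLY_CLASSES = ("DSF", "DSM")  # detector output classes; BC is background

DETECTIONS_CSV_HEADER = ["image_id", "x", "y", "class", "confidence"]


class FormatError(ValueError):
    """A file does not follow the expected on-disk format."""


class ValidationError(ValueError):
    """A value violates a domain invariant."""


class ClassVocabularyError(ValidationError):
    """A label outside the closed {DSM, DSF, BC} vocabulary."""


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box, 0-based half-open pixel coordinates."""

    xmin: int
    ymin: int
    xmax: int
    ymax: int
    label: str

    def __post_init__(self):
        if self.label not in CLASSES:
            raise ClassVocabularyError(
                f"unknown class {self.label!r}; expected one of {CLASSES}")
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValidationError(
                f"degenerate box ({self.xmin},{self.ymin},{self.xmax},{self.ymax})")

    @property
    def width(self) -> int:
        return self.xmax - self.xmin

    @property
    def height(self) -> int:
        return self.ymax - self.ymin

    @property
    def area(self) -> int:
        return self.width * self.height


def box_centroid(b: BBox) -> tuple[float, float]:
    """Centre of a box: ``((xmin+xmax)/2, (ymin+ymax)/2)``."""
    return ((b.xmin + b.xmax) / 2.0, (b.ymin + b.ymax) / 2.0)


@dataclass
class AnnotatedImage:
    image_id: str
    width: int
    height: int
    boxes: list[BBox] = field(default_factory=list)

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValidationError("image dimensions must be positive")
        for i, b in enumerate(self.boxes):
            if b.xmin < 0 or b.ymin < 0 or b.xmax > self.width or b.ymax > self.height:
                raise ValidationError(
                    f"object {i} box ({b.xmin},{b.ymin},{b.xmax},{b.ymax}) outside "
                    f"image {self.width}x{self.height}")

    def fly_boxes(self) -> list[BBox]:
        return [b for b in self.boxes if b.label in FLY_CLASSES]


@dataclass(frozen=True)
class Detection:
    """A point detection in full-image pixel coordinates."""

    x: float
    y: float
    pred_class: str
    confidence: float
    image_id: str = ""

    def __post_init__(self):
        if self.pred_class not in FLY_CLASSES:
            raise ClassVocabularyError(
                f"detections are {FLY_CLASSES} only, got {self.pred_class!r}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValidationError(f"confidence {self.confidence} outside [0, 1]")


@dataclass
class DatasetSplit:
    train: list[str]
    val: list[str]
    test: list[str]
    seed: int


# --------------------------------------------------------------------------
# Pascal VOC XML (LabelImg dialect)
# --------------------------------------------------------------------------

def read_voc_annotation(xml_path: str | Path) -> AnnotatedImage:
    """Parse a LabelImg-style Pascal VOC XML file.

    VOC stores 1-based inclusive coordinates; they are converted to the
    internal 0-based half-open convention here (xmin-1 and ymin-1, max
    unchanged). Unknown class names and out-of-image boxes are rejected.
    """
    xml_path = Path(xml_path)
    try:
        root = etree.parse(str(xml_path)).getroot()
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"{xml_path}: not well-formed XML: {exc}") from exc
    size = root.find("size")
    if size is None or size.find("width") is None or size.find("height") is None:
        raise FormatError(f"{xml_path}: missing size element")
    width = int(size.findtext("width"))
    height = int(size.findtext("height"))
    filename = root.findtext("filename") or xml_path.stem
    image_id = Path(filename).stem

    boxes = []
    for i, obj in enumerate(root.iter("object")):
        name = obj.findtext("name")
        if name not in CLASSES:
            raise ClassVocabularyError(
                f"{xml_path}: object {i} has unknown class {name!r}")
        bnd = obj.find("bndbox")
        if bnd is None:
            raise FormatError(f"{xml_path}: object {i} missing bndbox")
        xmin = int(round(float(bnd.findtext("xmin")))) - 1
        ymin = int(round(float(bnd.findtext("ymin")))) - 1
        xmax = int(round(float(bnd.findtext("xmax"))))
        ymax = int(round(float(bnd.findtext("ymax"))))
        try:
            box = BBox(xmin, ymin, xmax, ymax, name)
        except ValidationError as exc:
            raise ValidationError(f"{xml_path}: object {i}: {exc}") from exc
        if xmin < 0 or ymin < 0 or xmax > width or ymax > height:
            raise ValidationError(
                f"{xml_path}: object {i} box outside image {width}x{height}")
        boxes.append(box)
    return AnnotatedImage(image_id, width, height, boxes)


def write_voc_annotation(ann: AnnotatedImage, xml_path: str | Path) -> None:
    """Write an annotation as LabelImg-compatible Pascal VOC XML."""
    root = etree.Element("annotation")
    etree.SubElement(root, "folder").text = "images"
    etree.SubElement(root, "filename").text = f"{ann.image_id}.png"
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(ann.width)
    etree.SubElement(size, "height").text = str(ann.height)
    etree.SubElement(size, "depth").text = "3"
    for b in ann.boxes:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = b.label
        etree.SubElement(obj, "pose").text = "Unspecified"
        etree.SubElement(obj, "truncated").text = "0"
        etree.SubElement(obj, "difficult").text = "0"
        bnd = etree.SubElement(obj, "bndbox")
        etree.SubElement(bnd, "xmin").text = str(b.xmin + 1)
        etree.SubElement(bnd, "ymin").text = str(b.ymin + 1)
        etree.SubElement(bnd, "xmax").text = str(b.xmax)
        etree.SubElement(bnd, "ymax").text = str(b.ymax)
    tree = etree.ElementTree(root)
    tree.write(str(xml_path), pretty_print=True, encoding="utf-8",
               xml_declaration=False)


# --------------------------------------------------------------------------
# Dataset splitting
# --------------------------------------------------------------------------

def split_dataset(ids: list[str], fractions=(0.7, 0.2, 0.1), *,
                  seed: int) -> DatasetSplit:
    """Randomly partition image ids into train/val/test.

    Sizes follow largest-remainder rounding of ``len(ids) * fractions`` so
    the partition is exact. Deterministic for a given seed.
    """
    import numpy as np

    if not ids:
        raise ValidationError("ids must be non-empty")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError(f"fractions {fractions} do not sum to 1")
    n = len(ids)
    raw = [n * f for f in fractions]
    sizes = [int(r) for r in raw]
    remainders = [r - s for r, s in zip(raw, sizes)]
    for _ in range(n - sum(sizes)):
        i = max(range(3), key=lambda j: (remainders[j], -j))
        sizes[i] += 1
        remainders[i] = -1.0
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(n)]
    train = order[:sizes[0]]
    val = order[sizes[0]:sizes[0] + sizes[1]]
    test = order[sizes[0] + sizes[1]:]
    return DatasetSplit(train=train, val=val, test=test, seed=seed)


# --------------------------------------------------------------------------
# Detections CSV
# --------------------------------------------------------------------------

def write_detections_csv(dets: list[Detection], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(DETECTIONS_CSV_HEADER)
        for d in dets:
            writer.writerow([d.image_id, repr(float(d.x)), repr(float(d.y)),
                             d.pred_class, repr(float(d.confidence))])


def read_detections_csv(path: str | Path) -> list[Detection]:
    dets = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != DETECTIONS_CSV_HEADER:
            raise FormatError(f"{path}: bad header {header}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != 5:
                raise FormatError(f"{path}: line {lineno}: expected 5 fields")
            image_id, xs, ys, cls, conf = row
            try:
                det = Detection(x=float(xs), y=float(ys), pred_class=cls,
                                confidence=float(conf), image_id=image_id)
            except (ValueError, ValidationError) as exc:
                raise (exc if isinstance(exc, ValidationError)
                       else FormatError(f"{path}: line {lineno}: {exc}"))
            dets.append(det)
    return dets
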