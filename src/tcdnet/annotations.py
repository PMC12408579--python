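"""Bounding-box annotations, format dialects, and supervision matrices.

Object annotations are axis-aligned boxes in a 0-based, half-open pixel
convention: a box covers the pixel rectangle ``[x_min, x_max) × [y_min,
y_max)``, rows are y, columns are x.  Three interchange dialects are
supported — Labelme rectangle JSON, COCO detection JSON and normalized YOLO
text — and all are converted to this internal convention on read.

From an annotated image two binary supervision matrices are derived for the
counting loss: the *center matrix* ``T_L`` (one pixel per object, at the
object's center) and the *boundary matrix* ``T_B`` (pixels that the model
must predict as background, by default the one-pixel outline of every box).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

CATEGORY_NAME = "thrip"


class AnnotationError(ValueError):
    """Raised for malformed annotation records."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, 0-based half-open pixel coordinates."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self):
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise AnnotationError(f"degenerate box {self}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def center(self) -> tuple[float, float]:
        """(row, col) continuous center of the half-open box."""
        return ((self.y_min + self.y_max - 1) / 2.0, (self.x_min + self.x_max - 1) / 2.0)

    def center_pixel(self) -> tuple[int, int]:
        """(row, col) integer center pixel under the floor rule.

        Floor keeps the pixel inside the box even for 1-pixel boxes.
        """
        r, c = self.center()
        return int(np.floor(r)), int(np.floor(c))

    def pixel_footprint(self, height: int | None = None, width: int | None = None):
        """Integer pixel ranges (r0, r1, c0, c1), half-open, optionally clipped."""
        r0, r1 = int(np.floor(self.y_min)), int(np.ceil(self.y_max))
        c0, c1 = int(np.floor(self.x_min)), int(np.ceil(self.x_max))
        if height is not None:
            r0, r1 = max(r0, 0), min(r1, height)
            c0, c1 = max(c0, 0), min(c1, width)
        return r0, r1, c0, c1

    def clipped(self, width: int, height: int) -> "BoundingBox":
        return BoundingBox(max(self.x_min, 0.0), max(self.y_min, 0.0),
                           min(self.x_max, float(width)), min(self.y_max, float(height)))


@dataclass
class AnnotationSet:
    """All box annotations of one image."""

    image_id: str
    width: int
    height: int
    boxes: list[BoundingBox] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.boxes)

    def flipped(self, horizontal: bool = False, vertical: bool = False) -> "AnnotationSet":
        boxes = []
        for b in self.boxes:
            x0, x1, y0, y1 = b.x_min, b.x_max, b.y_min, b.y_max
            if horizontal:
                x0, x1 = self.width - b.x_max, self.width - b.x_min
            if vertical:
                y0, y1 = self.height - b.y_max, self.height - b.y_min
            boxes.append(BoundingBox(x0, y0, x1, y1))
        return AnnotationSet(self.image_id, self.width, self.height, boxes)

    def scaled(self, factor: float) -> "AnnotationSet":
        """Boxes and image size multiplied by ``factor`` (e.g. after
        resampling the image)."""
        if factor <= 0:
            raise ValueError(f"scale factor must be positive, got {factor}")
        boxes = [BoundingBox(b.x_min * factor, b.y_min * factor,
                             b.x_max * factor, b.y_max * factor)
                 for b in self.boxes]
        return AnnotationSet(self.image_id, int(round(self.width * factor)),
                             int(round(self.height * factor)), boxes)


@dataclass
class CenterMatrix:
    """Binary H×W matrix with a single 1 at every object center (T_L)."""

    values: np.ndarray

    @property
    def n_centers(self) -> int:
        return int(self.values.sum())


@dataclass
class BoundaryMatrix:
    """Binary H×W matrix of pixels supervised toward background (T_B)."""

    values: np.ndarray


def _clip_box(box: BoundingBox, width: int, height: int, where: str) -> BoundingBox | None:
    if box.x_min < 0 or box.y_min < 0 or box.x_max > width or box.y_max > height:
        warnings.warn(f"{where}: box {box} outside {width}x{height} image, clipping")
        try:
            return box.clipped(width, height)
        except AnnotationError:
            warnings.warn(f"{where}: box {box} entirely outside image, dropped")
            return None
    return box


# ---------------------------------------------------------------------------
# supervision matrices
# ---------------------------------------------------------------------------


def build_center_matrix(ann: AnnotationSet) -> CenterMatrix:
    """T_L: 1 at the integer center pixel of each box, 0 elsewhere.

    Centers that fall outside the image are skipped; coinciding centers
    collapse to a single pixel (with a warning), so ``sum(T_L)`` can be
    smaller than the number of boxes in pathological overlaps.
    """
    m = np.zeros((ann.height, ann.width), dtype=np.uint8)
    collapsed = 0
    for b in ann.boxes:
        r, c = b.center_pixel()
        if 0 <= r < ann.height and 0 <= c < ann.width:
            if m[r, c]:
                collapsed += 1
            m[r, c] = 1
    if collapsed:
        warnings.warn(f"{ann.image_id}: {collapsed} duplicate object centers collapsed")
    return CenterMatrix(m)


def build_boundary_matrix(ann: AnnotationSet, mode: str = "perimeter") -> BoundaryMatrix:
    """T_B: background-supervised pixels derived from the boxes.

    mode="perimeter" (default): the one-pixel-wide outline of every box;
    outline pixels falling strictly inside another box's interior are
    dropped so supervision never contradicts a positive region.
    mode="complement": every pixel outside all box footprints.
    """
    h, w = ann.height, ann.width
    if mode == "complement":
        inside = np.zeros((h, w), dtype=bool)
        for b in ann.boxes:
            r0, r1, c0, c1 = b.pixel_footprint(h, w)
            inside[r0:r1, c0:c1] = True
        return BoundaryMatrix((~inside).astype(np.uint8))
    if mode != "perimeter":
        raise ValueError(f"unknown boundary mode {mode!r}")

    perim = np.zeros((h, w), dtype=bool)
    interior = np.zeros((h, w), dtype=bool)
    for b in ann.boxes:
        r0, r1, c0, c1 = b.pixel_footprint(h, w)
        if r1 <= r0 or c1 <= c0:
            continue
        perim[r0:r1, c0] = True
        perim[r0:r1, c1 - 1] = True
        perim[r0, c0:c1] = True
        perim[r1 - 1, c0:c1] = True
        if r1 - r0 > 2 and c1 - c0 > 2:
            interior[r0 + 1:r1 - 1, c0 + 1:c1 - 1] = True
    return BoundaryMatrix((perim & ~interior).astype(np.uint8))


# ---------------------------------------------------------------------------
# dataset split
# ---------------------------------------------------------------------------


def split_dataset(anns: list, ratios=(0.6, 0.2, 0.2), seed: int = 0):
    """Deterministic shuffled partition into len(ratios) parts.

    Part boundaries are floors of the cumulative ratio shares, so e.g. 5618
    images at 6:2:2 give parts of 3370/1124/1124.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    n = len(anns)
    if n < len(ratios):
        raise ValueError(f"cannot split {n} items into {len(ratios)} parts")
    order = np.random.default_rng(seed).permutation(n)
    bounds = [0] + [int(np.floor(n * c)) for c in np.cumsum(ratios)]
    bounds[-1] = n
    return tuple([anns[i] for i in order[lo:hi]]
                 for lo, hi in zip(bounds[:-1], bounds[1:]))


def split_sizes(n: int, ratios=(0.6, 0.2, 0.2)) -> tuple[int, ...]:
    """Part sizes produced by :func:`split_dataset` without shuffling."""
    bounds = [0] + [int(np.floor(n * c)) for c in np.cumsum(ratios)]
    bounds[-1] = n
    return tuple(hi - lo for lo, hi in zip(bounds[:-1], bounds[1:]))


# ---------------------------------------------------------------------------
# dialect readers
# ---------------------------------------------------------------------------


def read_annotations(path, dialect: str, image_size: tuple[int, int] | None = None) -> list[AnnotationSet]:
    """Read annotations from ``path`` under the named dialect.

    ``path`` may be a single file or a directory (all matching files, sorted
    by name).  For YOLO text files the image size is taken from an adjacent
    image with the same stem, or from ``image_size`` as (width, height).
    """
    path = Path(path)
    readers = {"labelme": _read_labelme, "coco": _read_coco, "yolo": _read_yolo}
    if dialect not in readers:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(readers)}")
    if path.is_dir():
        patterns = {"labelme": "*.json", "coco": "*.json", "yolo": "*.txt"}
        out = []
        for f in sorted(path.glob(patterns[dialect])):
            out.extend(readers[dialect](f, image_size))
        return out
    if not path.exists():
        raise FileNotFoundError(path)
    return readers[dialect](path, image_size)


def _read_labelme(path: Path, image_size) -> list[AnnotationSet]:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        w, h = int(doc["imageWidth"]), int(doc["imageHeight"])
    except KeyError as e:
        raise AnnotationError(f"{path}: labelme file missing {e}") from None
    boxes = []
    for i, shape in enumerate(doc.get("shapes", [])):
        try:
            if shape.get("shape_type", "rectangle") != "rectangle":
                raise KeyError("shape_type")
            (x1, y1), (x2, y2) = shape["points"]
            box = BoundingBox(min(x1, x2), min(y1, y2), max(x1, x2), max(y1, y2))
        except (KeyError, TypeError, ValueError, AnnotationError) as e:
            raise AnnotationError(f"{path}: labelme record {i} malformed: {e}") from None
        box = _clip_box(box, w, h, f"{path} record {i}")
        if box is not None:
            boxes.append(box)
    image_id = doc.get("imagePath", path.stem)
    return [AnnotationSet(Path(image_id).stem, w, h, boxes)]


def _read_coco(path: Path, image_size) -> list[AnnotationSet]:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        images = {im["id"]: im for im in doc["images"]}
    except (KeyError, TypeError) as e:
        raise AnnotationError(f"{path}: COCO file missing images section: {e}") from None
    sets = {iid: AnnotationSet(Path(im.get("file_name", str(iid))).stem,
                               int(im["width"]), int(im["height"]))
            for iid, im in images.items()}
    for i, rec in enumerate(doc.get("annotations", [])):
        try:
            iid = rec["image_id"]
            x, y, bw, bh = rec["bbox"]
            box = BoundingBox(x, y, x + bw, y + bh)
        except (KeyError, TypeError, ValueError, AnnotationError) as e:
            raise AnnotationError(f"{path}: COCO annotation {i} malformed: {e}") from None
        if iid not in sets:
            raise AnnotationError(f"{path}: COCO annotation {i} references unknown image {iid}")
        a = sets[iid]
        box = _clip_box(box, a.width, a.height, f"{path} annotation {i}")
        if box is not None:
            a.boxes.append(box)
    return [sets[iid] for iid in sorted(sets)]


_IMG_SUFFIXES = (".png", ".jpg", ".jpeg")


def _read_yolo(path: Path, image_size) -> list[AnnotationSet]:
    if image_size is None:
        for suf in _IMG_SUFFIXES:
            img = path.with_suffix(suf)
            if img.exists():
                from PIL import Image
                with Image.open(img) as im:
                    image_size = im.size
                break
    if image_size is None:
        raise AnnotationError(
            f"{path}: YOLO dialect needs an image size (no adjacent image found)")
    w, h = image_size
    boxes = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise AnnotationError(f"{path}: YOLO record {i} malformed: {line!r}")
            try:
                _, cx, cy, bw, bh = (float(p) for p in parts)
                box = BoundingBox((cx - bw / 2) * w, (cy - bh / 2) * h,
                                  (cx + bw / 2) * w, (cy + bh / 2) * h)
            except (ValueError, AnnotationError) as e:
                raise AnnotationError(f"{path}: YOLO record {i} malformed: {e}") from None
            box = _clip_box(box, w, h, f"{path} record {i}")
            if box is not None:
                boxes.append(box)
    return [AnnotationSet(path.stem, w, h, boxes)]


# ---------------------------------------------------------------------------
# dialect writers
# ---------------------------------------------------------------------------


def write_annotations(anns: list[AnnotationSet], out_dir, dialect: str) -> list[Path]:
    """Write annotations under ``out_dir``; returns the files written.

    Labelme and YOLO write one file per image; COCO writes a single
    ``annotations.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if dialect == "labelme":
        files = []
        for a in anns:
            doc = {
                "version": "5.0.0",
                "imagePath": f"{a.image_id}.png",
                "imageHeight": a.height,
                "imageWidth": a.width,
                "imageData": None,
                "shapes": [
                    {"label": CATEGORY_NAME, "shape_type": "rectangle",
                     "points": [[b.x_min, b.y_min], [b.x_max, b.y_max]]}
                    for b in a.boxes
                ],
            }
            f = out_dir / f"{a.image_id}.json"
            f.write_text(json.dumps(doc, indent=1))
            files.append(f)
        return files
    if dialect == "coco":
        doc = {
            "images": [{"id": i, "file_name": f"{a.image_id}.png",
                        "width": a.width, "height": a.height}
                       for i, a in enumerate(anns)],
            "annotations": [],
            "categories": [{"id": 1, "name": CATEGORY_NAME}],
        }
        k = 0
        for i, a in enumerate(anns):
            for b in a.boxes:
                doc["annotations"].append(
                    {"id": k, "image_id": i, "category_id": 1,
                     "bbox": [b.x_min, b.y_min, b.width, b.height],
                     "area": b.area, "iscrowd": 0})
                k += 1
        f = out_dir / "annotations.json"
        f.write_text(json.dumps(doc))
        return [f]
    if dialect == "yolo":
        files = []
        for a in anns:
            lines = []
            for b in a.boxes:
                cx = (b.x_min + b.x_max) / 2 / a.width
                cy = (b.y_min + b.y_max) / 2 / a.height
                lines.append(f"0 {cx:.10g} {cy:.10g} "
                             f"{b.width / a.width:.10g} {b.height / a.height:.10g}")
            f = out_dir / f"{a.image_id}.txt"
            f.write_text("\n".join(lines) + ("\n" if lines else ""))
            files.append(f)
        return files
    raise ValueError(f"unknown dialect {dialect!r}")
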