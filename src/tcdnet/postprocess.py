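"""From probability map to detections: threshold, label, centroid, count.

The predicted count of an image is the number of connected regions in the
thresholded probability map; each region's detection is its centroid (the
arithmetic mean of member pixel coordinates, computed by histogram counting
and coordinate accumulation) with the region's mean probability as its
confidence.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .model import ProbabilityMap

_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


@dataclass
class LabelMatrix:
    """Integer H×W matrix; 0 is background, regions are labeled 1..n_labels
    in row-major order of their first pixel."""

    values: np.ndarray
    n_labels: int


@dataclass(frozen=True)
class Detection:
    row: float
    col: float
    area: int
    confidence: float = 1.0


@dataclass
class DetectionSet:
    detections: list[Detection] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.detections)

    def __iter__(self):
        return iter(self.detections)

    def __len__(self):
        return len(self.detections)


def _values(p) -> np.ndarray:
    return p.values if isinstance(p, ProbabilityMap) else np.asarray(p)


def binarize(p, threshold: float = 0.5) -> np.ndarray:
    """Boolean mask of pixels with probability >= threshold (inclusive)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return _values(p) >= threshold


def label_components(mask: np.ndarray, connectivity: int = 4) -> LabelMatrix:
    """Label maximal connected regions of a binary mask.

    Labels are renumbered so that region k's first pixel (row-major) precedes
    region k+1's, making the labeling deterministic by construction.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    if n > 1:
        flat = labels.ravel()
        first = np.full(n + 1, flat.size, dtype=np.int64)
        nz = np.flatnonzero(flat)
        # reversed so the earliest index wins
        first[flat[nz[::-1]]] = nz[::-1]
        order = np.argsort(first[1:], kind="stable")
        remap = np.zeros(n + 1, dtype=labels.dtype)
        remap[1 + order] = np.arange(1, n + 1)
        labels = remap[labels]
    return LabelMatrix(labels, int(n))


def centroids(labels: LabelMatrix, probabilities: np.ndarray | None = None) -> DetectionSet:
    """Centroid, area and (optionally) mean-probability confidence per region.

    Computed by per-label histograms: pixel counts via bincount, coordinate
    sums via bincount weighted by the flattened row/column index grids.
    """
    n = labels.n_labels
    if n == 0:
        return DetectionSet()
    lab = labels.values.ravel()
    h, w = labels.values.shape
    rows, cols = np.indices((h, w))
    counts = np.bincount(lab, minlength=n + 1)[1:]
    rsum = np.bincount(lab, weights=rows.ravel(), minlength=n + 1)[1:]
    csum = np.bincount(lab, weights=cols.ravel(), minlength=n + 1)[1:]
    if probabilities is not None:
        psum = np.bincount(lab, weights=np.asarray(probabilities).ravel(),
                           minlength=n + 1)[1:]
        conf = psum / counts
    else:
        conf = np.ones(n)
    dets = [Detection(rsum[k] / counts[k], csum[k] / counts[k],
                      int(counts[k]), float(conf[k]))
            for k in range(n)]
    return DetectionSet(dets)


def detect_and_count(p, threshold: float = 0.5, connectivity: int = 4,
                     min_area: int = 1) -> DetectionSet:
    """Full post-processing: binarize → label → area-filter → centroids."""
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    values = _values(p)
    labels = label_components(binarize(values, threshold), connectivity)
    dets = centroids(labels, probabilities=values)
    if min_area > 1:
        dets = DetectionSet([d for d in dets if d.area >= min_area])
    return dets


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def write_csv(results: dict[str, DetectionSet], path) -> None:
    """Predictions as CSV rows (image_id, row, col, area, confidence)."""
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["image_id", "row", "col", "area", "confidence"])
        for image_id, dets in results.items():
            for d in dets:
                wr.writerow([image_id, f"{d.row:.3f}", f"{d.col:.3f}",
                             d.area, f"{d.confidence:.5f}"])


def write_coco_results(results: dict[str, DetectionSet], image_ids: dict[str, int],
                       path) -> None:
    """COCO detection-results JSON; each point becomes a 1×1 box."""
    out = []
    for image_id, dets in results.items():
        for d in dets:
            out.append({"image_id": image_ids[image_id], "category_id": 1,
                        "bbox": [d.col - 0.5, d.row - 0.5, 1.0, 1.0],
                        "score": d.confidence})
    Path(path).write_text(json.dumps(out))
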