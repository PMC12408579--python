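"""Detection matching and the evaluation metric suite.

A detection is a true positive when its centroid lies inside a ground-truth
box that no higher-confidence detection has already claimed; matching is
one-to-one, greedy in confidence order.  Detection quality is summarised by
precision/recall/F1 (micro-averaged over a dataset), counting quality by
MAE, RMSE and R².

Two R² variants are reported: the standard coefficient of determination
1 - SS_res/SS_tot (the default), and a variance-ratio form
sum((pred - mean_gt)^2) / sum((gt - mean_gt)^2) kept for comparability with
reports that use it; the latter can exceed 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .annotations import AnnotationSet
from .postprocess import DetectionSet


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    det_is_tp: list[bool] = field(default_factory=list)
    box_matched_by: list[int | None] = field(default_factory=list)

    def __add__(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass
class MetricsReport:
    precision: float
    recall: float
    f1: float
    mae: float
    rmse: float
    r2_standard: float
    r2_eq_variance_ratio: float
    n_images: int
    tp: int
    fp: int
    fn: int

    def as_dict(self) -> dict:
        return dict(vars(self))


def _box_contains(box, row: float, col: float) -> bool:
    return box.x_min <= col < box.x_max and box.y_min <= row < box.y_max


def match_detections(dets: DetectionSet, gt: AnnotationSet) -> MatchResult:
    """One-to-one greedy matching in descending confidence order.

    Each detection claims the still-unclaimed ground-truth box containing
    its centroid; with several candidates, the box whose center is nearest
    wins.  Ties in confidence break row-major by centroid.
    """
    order = sorted(range(len(dets.detections)),
                   key=lambda i: (-dets.detections[i].confidence,
                                  dets.detections[i].row, dets.detections[i].col))
    claimed = [False] * len(gt.boxes)
    matched_by: list[int | None] = [None] * len(gt.boxes)
    det_is_tp = [False] * len(dets.detections)
    for i in order:
        d = dets.detections[i]
        best, best_d2 = None, None
        for j, box in enumerate(gt.boxes):
            if claimed[j] or not _box_contains(box, d.row, d.col):
                continue
            cr, cc = box.center()
            d2 = (cr - d.row) ** 2 + (cc - d.col) ** 2
            if best is None or d2 < best_d2:
                best, best_d2 = j, d2
        if best is not None:
            claimed[best] = True
            matched_by[best] = i
            det_is_tp[i] = True
    tp = sum(det_is_tp)
    return MatchResult(tp, len(dets.detections) - tp, len(gt.boxes) - tp,
                       det_is_tp, matched_by)


def precision_recall_f1(m: MatchResult) -> tuple[float, float, float]:
    """Eqs: P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2TP/(2TP+FP+FN); zero
    denominators give 0 by convention."""
    p = m.tp / (m.tp + m.fp) if m.tp + m.fp else 0.0
    r = m.tp / (m.tp + m.fn) if m.tp + m.fn else 0.0
    f1 = 2 * m.tp / (2 * m.tp + m.fp + m.fn) if 2 * m.tp + m.fp + m.fn else 0.0
    return p, r, f1


def counting_metrics(gt_counts, pred_counts) -> tuple[float, float, float, float]:
    """MAE, RMSE, standard R², and the variance-ratio R² over per-image counts."""
    gt = np.asarray(gt_counts, dtype=float)
    pred = np.asarray(pred_counts, dtype=float)
    if gt.shape != pred.shape:
        raise ValueError(f"count lists differ in length: {gt.shape} vs {pred.shape}")
    err = gt - pred
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err ** 2).mean()))
    ss_tot = float(((gt - gt.mean()) ** 2).sum())
    if ss_tot == 0.0:
        r2_std = 1.0 if np.allclose(gt, pred) else 0.0
        r2_ratio = r2_std
    else:
        r2_std = 1.0 - float((err ** 2).sum()) / ss_tot
        r2_ratio = float(((pred - gt.mean()) ** 2).sum()) / ss_tot
    return mae, rmse, r2_std, r2_ratio


def evaluate_dataset(predictions: dict[str, DetectionSet],
                     annotations: list[AnnotationSet]) -> MetricsReport:
    """Aggregate metrics over a dataset.

    TP/FP/FN are pooled over all images before computing P/R/F1
    (micro-average); counting metrics use the per-image count vectors.
    A missing prediction counts as zero detections (with a warning).
    """
    if not annotations:
        raise ValueError("cannot evaluate an empty dataset")
    total = MatchResult(0, 0, 0)
    gt_counts, pred_counts = [], []
    for ann in annotations:
        dets = predictions.get(ann.image_id)
        if dets is None:
            warnings.warn(f"no prediction for image {ann.image_id}; assuming empty")
            dets = DetectionSet()
        total = total + match_detections(dets, ann)
        gt_counts.append(ann.count)
        pred_counts.append(dets.count)
    p, r, f1 = precision_recall_f1(total)
    mae, rmse, r2_std, r2_ratio = counting_metrics(gt_counts, pred_counts)
    return MetricsReport(p, r, f1, mae, rmse, r2_std, r2_ratio,
                         len(annotations), total.tp, total.fp, total.fn)
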