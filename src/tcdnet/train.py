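"""Training loop, validation cadence and prediction.

Training follows the counting-loss recipe: batch size 1, Adam (lr 1e-5,
weight decay 1e-4 at full scale), random horizontal/vertical flips applied
jointly to the image and both supervision matrices, and periodic validation
through the full post-processing + matching pipeline; the checkpoint with
the best validation F1 (at the 0.5 inference threshold) is kept.

Images enter the network as float32 (C, H, W) scaled to [-1, 1].
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._tensor import Tensor
from .annotations import (AnnotationSet, build_boundary_matrix,
                          build_center_matrix)
from .loss import LossBreakdown, oc_loss
from .metrics import evaluate_dataset
from .model import TCDNet
from .nn import Adam
from .postprocess import DetectionSet, detect_and_count

Sample = tuple[np.ndarray, AnnotationSet]


@dataclass
class TrainConfig:
    lr: float = 1e-5
    weight_decay: float = 1e-4
    batch_size: int = 1
    epochs: int = 100
    flip_horizontal: bool = True
    flip_vertical: bool = True
    eval_every: int = 5
    seed: int = 0
    fp_threshold: float = 0.5
    threshold: float = 0.5          # inference threshold for validation
    connectivity: int = 4
    min_area: int = 1
    boundary_mode: str = "perimeter"
    lambda_mode: str = "count_minus_one"
    loss_terms: tuple[str, ...] = ("localization", "boundary", "false_positive")
    lr_schedule: str = "constant"   # "constant" | "cosine"
    lr_final_fraction: float = 0.05  # cosine floor, as a fraction of lr

    def lr_at(self, epoch: int) -> float:
        """Learning rate for ``epoch`` (1-based)."""
        if self.lr_schedule == "constant" or self.epochs <= 1:
            return self.lr
        if self.lr_schedule != "cosine":
            raise ValueError(f"unknown lr schedule {self.lr_schedule!r}")
        t = (epoch - 1) / (self.epochs - 1)
        lo = self.lr * self.lr_final_fraction
        return lo + (self.lr - lo) * 0.5 * (1.0 + np.cos(np.pi * t))

    @staticmethod
    def desk_scale(**overrides) -> "TrainConfig":
        """Faster-converging settings for small synthetic runs on CPU."""
        cfg = TrainConfig(lr=3e-4, epochs=40, eval_every=2)
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg


@dataclass
class TrainLog:
    steps: list[dict] = field(default_factory=list)     # per-image loss terms
    evals: list[dict] = field(default_factory=list)     # per-eval val metrics

    def epoch_losses(self) -> list[dict]:
        """Mean loss terms per epoch."""
        by_epoch: dict[int, list[dict]] = {}
        for s in self.steps:
            by_epoch.setdefault(s["epoch"], []).append(s)
        out = []
        for e in sorted(by_epoch):
            rows = by_epoch[e]
            out.append({
                "epoch": e,
                **{k: float(np.mean([r[k] for r in rows]))
                   for k in ("localization", "boundary", "false_positive", "total")},
            })
        return out

    def write_csv(self, path) -> None:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["epoch", "image", "localization", "boundary",
                         "false_positive", "total"])
            for s in self.steps:
                wr.writerow([s["epoch"], s["image"], s["localization"],
                             s["boundary"], s["false_positive"], s["total"]])
        with open(path.with_name(path.stem + "_val.csv"), "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["epoch", "f1", "precision", "recall", "mae", "rmse", "fp"])
            for e in self.evals:
                wr.writerow([e["epoch"], e["f1"], e["precision"], e["recall"],
                             e["mae"], e["rmse"], e["fp"]])


def to_input(image: np.ndarray) -> np.ndarray:
    """HWC uint8/float image → float32 CHW in [-1, 1]."""
    img = np.asarray(image)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.dtype == np.uint8:
        img = img.astype(np.float32) / 255.0
    return (img.astype(np.float32).transpose(2, 0, 1) * 2.0) - 1.0


def _flip_sample(image: np.ndarray, ann: AnnotationSet,
                 horizontal: bool, vertical: bool) -> Sample:
    img = image
    if horizontal:
        img = img[:, ::-1]
    if vertical:
        img = img[::-1]
    return np.ascontiguousarray(img), ann.flipped(horizontal, vertical)


def train_step(model: TCDNet, optimizer: Adam, image: np.ndarray,
               ann: AnnotationSet, cfg: TrainConfig) -> LossBreakdown:
    """One forward/backward/update on a single annotated image."""
    t_l = build_center_matrix(ann)
    t_b = build_boundary_matrix(ann, mode=cfg.boundary_mode)
    pmap = model(Tensor(to_input(image)))
    breakdown = oc_loss(pmap, t_l, t_b, fp_threshold=cfg.fp_threshold,
                        connectivity=cfg.connectivity,
                        lambda_mode=cfg.lambda_mode, terms=cfg.loss_terms)
    for name in ("localization", "boundary", "false_positive"):
        if not np.isfinite(getattr(breakdown, name)):
            raise FloatingPointError(
                f"non-finite {name} loss on image {ann.image_id}")
    if breakdown.total_tensor is not None:
        optimizer.zero_grad()
        breakdown.total_tensor.backward()
        optimizer.step()
    return breakdown


def validate(model: TCDNet, data: list[Sample], cfg: TrainConfig) -> dict:
    preds = {}
    for image, ann in data:
        pmap = model(Tensor(to_input(image)))
        preds[ann.image_id] = detect_and_count(
            pmap, threshold=cfg.threshold,
            connectivity=cfg.connectivity, min_area=cfg.min_area)
    report = evaluate_dataset(preds, [a for _, a in data])
    return report.as_dict()


def train(model: TCDNet, train_data: list[Sample], val_data: list[Sample],
          cfg: TrainConfig, checkpoint_path=None,
          verbose: bool = False) -> tuple[TrainLog, dict]:
    """Train ``model`` in place; returns the log and the best state dict
    (by validation F1; falls back to the final state if never evaluated)."""
    if cfg.batch_size != 1:
        raise ValueError("only batch size 1 is supported")
    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    log = TrainLog()
    best_f1, best_state = -1.0, None

    for epoch in range(1, cfg.epochs + 1):
        optimizer.lr = cfg.lr_at(epoch)
        order = rng.permutation(len(train_data))
        for idx in order:
            image, ann = train_data[idx]
            fh = cfg.flip_horizontal and bool(rng.integers(2))
            fv = cfg.flip_vertical and bool(rng.integers(2))
            img, a = _flip_sample(image, ann, fh, fv)
            breakdown = train_step(model, optimizer, img, a, cfg)
            log.steps.append({
                "epoch": epoch, "image": ann.image_id,
                "localization": breakdown.localization,
                "boundary": breakdown.boundary,
                "false_positive": breakdown.false_positive,
                "total": breakdown.total,
            })
        if val_data and (epoch % cfg.eval_every == 0 or epoch == cfg.epochs):
            report = validate(model, val_data, cfg)
            report["epoch"] = epoch
            log.evals.append(report)
            if verbose:
                print(f"epoch {epoch}: F1={report['f1']:.3f} "
                      f"MAE={report['mae']:.2f} FP={report['fp']}", flush=True)
            if report["f1"] >= best_f1:
                best_f1 = report["f1"]
                best_state = model.state_dict()
                if checkpoint_path is not None:
                    np.savez(checkpoint_path, **best_state)
    if best_state is None:
        best_state = model.state_dict()
        if checkpoint_path is not None:
            np.savez(checkpoint_path, **best_state)
    return log, best_state


def upsample_samples(data: list[Sample], factor: int) -> list[Sample]:
    """Bilinearly upsample images by an integer factor and scale the box
    annotations to match.

    Raising the input resolution relative to the object size makes
    near-resolution-limit objects detectable by the stride-4 heads; it is
    the training-time counterpart of running large native inputs.
    """
    from PIL import Image

    if factor == 1:
        return list(data)
    if factor < 1:
        raise ValueError(f"upsample factor must be >= 1, got {factor}")
    out = []
    for image, ann in data:
        h, w = image.shape[:2]
        im = Image.fromarray(image).resize((w * factor, h * factor),
                                           Image.BILINEAR)
        out.append((np.asarray(im), ann.scaled(factor)))
    return out


def pad_to_multiple(image: np.ndarray, multiple: int = 32) -> tuple[np.ndarray, int, int]:
    """Reflect-pad an HWC image so both sides divide ``multiple``."""
    h, w = image.shape[:2]
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph or pw:
        warnings.warn(f"padding image from {h}x{w} to {h + ph}x{w + pw}")
        image = np.pad(image, ((0, ph), (0, pw), (0, 0)), mode="reflect")
    return image, h, w


def predict(model: TCDNet, image: np.ndarray, threshold: float = 0.5,
            connectivity: int = 4, min_area: int = 1,
            return_probability: bool = False):
    """Detections for one HWC image; pads to a multiple of 32 if needed and
    drops detections whose centroid falls in the padding."""
    padded, h, w = pad_to_multiple(image)
    pmap = model(Tensor(to_input(padded)))
    dets = detect_and_count(pmap, threshold=threshold,
                            connectivity=connectivity, min_area=min_area)
    dets = DetectionSet([d for d in dets if d.row < h and d.col < w])
    if return_probability:
        return dets, pmap.values[:h, :w]
    return dets
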