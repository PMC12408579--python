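"""Seeded generator of leaf-like scenes with tiny dark elliptical objects.

The generator emulates the statistics of greenhouse thrips imagery: a
textured green background (low-frequency gradient plus smoothed noise), a
truncated-Poisson number of objects per image (mean 8.5), and each object a
small rotated dark ellipse whose tight bounding box covers far less than
0.1% of the image.  Everything is reproducible from an integer seed, and
datasets are written as PNGs with annotations in all three dialects.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .annotations import (AnnotationSet, BoundingBox, split_dataset,
                          write_annotations)


@dataclass
class SceneConfig:
    image_size: int = 256
    count_mean: float = 8.5
    count_max: int = 16
    object_axis_range: tuple[float, float] = (2.0, 9.0)   # ellipse axis lengths, px
    contrast_range: tuple[float, float] = (0.4, 0.8)      # relative darkening
    background_gradient: float = 0.08                     # ramp amplitude
    background_texture: float = 0.05                      # smoothed-noise amplitude
    texture_scale: float = 6.0                            # smoothing sigma, px
    noise_sigma: float = 0.015                            # per-pixel additive noise
    min_separation: float = 14.0                          # between object centers, px
    alpha_threshold: float = 0.1   # coverage above which a pixel counts as rendered

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True)
                              .encode()).hexdigest()[:16]


def sample_count(cfg: SceneConfig, rng: np.random.Generator) -> int:
    """Object count: Poisson(count_mean) truncated to [0, count_max]."""
    return int(min(rng.poisson(cfg.count_mean), cfg.count_max))


def _background(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.image_size
    g = rng.uniform(0.45, 0.7)
    base = np.array([0.55 * g, g, 0.45 * g])
    yy, xx = np.mgrid[0:n, 0:n] / n
    gx, gy = rng.uniform(-1, 1, 2) * cfg.background_gradient
    ramp = gx * xx + gy * yy
    tex = gaussian_filter(rng.normal(0, 1, (n, n)), cfg.texture_scale)
    std = tex.std()
    if std > 0:
        tex *= cfg.background_texture / std
    img = base[None, None, :] + (ramp + tex)[:, :, None]
    return img


def _render_ellipse(img: np.ndarray, cy: float, cx: float, a: float, b: float,
                    theta: float, color: np.ndarray, cfg: SceneConfig,
                    supersample: int = 4) -> BoundingBox | None:
    """Alpha-composite an anti-aliased rotated ellipse; return the tight box
    of pixels with coverage above the threshold, or None if empty."""
    n = img.shape[0]
    r = max(a, b) / 2 + 1.5
    r0, r1 = max(int(np.floor(cy - r)), 0), min(int(np.ceil(cy + r)) + 1, n)
    c0, c1 = max(int(np.floor(cx - r)), 0), min(int(np.ceil(cx + r)) + 1, n)
    if r1 <= r0 or c1 <= c0:
        return None
    s = supersample
    off = (np.arange(s) + 0.5) / s - 0.5
    rows = (np.arange(r0, r1)[:, None] + off[None, :]).ravel()
    cols = (np.arange(c0, c1)[:, None] + off[None, :]).ravel()
    dy = rows[:, None] - cy
    dx = cols[None, :] - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / (a / 2)) ** 2 + (v / (b / 2)) ** 2 <= 1.0
    alpha = inside.reshape(r1 - r0, s, c1 - c0, s).mean(axis=(1, 3))
    covered = alpha >= cfg.alpha_threshold
    if not covered.any():
        return None
    img[r0:r1, c0:c1] = (img[r0:r1, c0:c1] * (1 - alpha[:, :, None])
                         + color[None, None, :] * alpha[:, :, None])
    ys, xs = np.nonzero(covered)
    return BoundingBox(float(c0 + xs.min()), float(r0 + ys.min()),
                       float(c0 + xs.max() + 1), float(r0 + ys.max() + 1))


def generate_scene(cfg: SceneConfig, seed) -> tuple[np.ndarray, AnnotationSet]:
    """One scene: (H, W, 3) uint8 image and its tight-box annotations.

    ``seed`` may be an int or a sequence (e.g. ``[dataset_seed, index]``);
    the same seed always reproduces the same bytes.
    """
    rng = np.random.default_rng(seed)
    n = cfg.image_size
    img = _background(cfg, rng)
    n_objects = sample_count(cfg, rng)

    centers: list[tuple[float, float]] = []
    boxes: list[BoundingBox] = []
    margin = cfg.object_axis_range[1]
    placed = 0
    for _ in range(n_objects):
        ok = False
        for _attempt in range(60):
            cy = rng.uniform(margin, n - margin)
            cx = rng.uniform(margin, n - margin)
            if all((cy - py) ** 2 + (cx - px) ** 2 >= cfg.min_separation ** 2
                   for py, px in centers):
                ok = True
                break
        if not ok:
            warnings.warn(f"could not place object {placed + 1}/{n_objects}; "
                          "scene will contain fewer objects")
            continue
        a = rng.uniform(*cfg.object_axis_range)
        b = rng.uniform(cfg.object_axis_range[0], a)
        theta = rng.uniform(0, np.pi)
        contrast = rng.uniform(*cfg.contrast_range)
        base = img[int(cy), int(cx)]
        color = base * (1.0 - contrast)
        box = _render_ellipse(img, cy, cx, a, b, theta, color, cfg)
        if box is not None:
            centers.append((cy, cx))
            boxes.append(box)
            placed += 1

    if cfg.noise_sigma > 0:
        img = img + rng.normal(0, cfg.noise_sigma, img.shape)
    img8 = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
    ann = AnnotationSet("scene", n, n, boxes)
    return img8, ann


def generate_scenes(cfg: SceneConfig, n_images: int, seed: int,
                    prefix: str = "scene") -> list[tuple[np.ndarray, AnnotationSet]]:
    """A list of reproducible scenes with stable image ids."""
    out = []
    for i in range(n_images):
        img, ann = generate_scene(cfg, [int(seed), i])
        ann.image_id = f"{prefix}_{i:05d}"
        out.append((img, ann))
    return out


def generate_dataset(cfg: SceneConfig, n_images: int, out_dir,
                     split_ratios=(0.6, 0.2, 0.2), seed: int = 0,
                     overwrite: bool = False) -> dict:
    """Write a full dataset: PNGs, the three annotation dialects, split
    lists and a manifest.  Returns the manifest dict."""
    if n_images < len(split_ratios):
        raise ValueError(f"need at least {len(split_ratios)} images")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} is not empty (pass overwrite=True)")
    (out_dir / "images").mkdir(parents=True, exist_ok=True)

    scenes = generate_scenes(cfg, n_images, seed)
    anns = []
    for img, ann in scenes:
        Image.fromarray(img).save(out_dir / "images" / f"{ann.image_id}.png")
        anns.append(ann)
    write_annotations(anns, out_dir / "labelme", "labelme")
    write_annotations(anns, out_dir / "coco", "coco")
    write_annotations(anns, out_dir / "yolo", "yolo")

    splits = split_dataset(anns, split_ratios, seed)
    names = ("train", "val", "test")[: len(splits)]
    split_counts = {}
    for name, part in zip(names, splits):
        (out_dir / f"{name}.txt").write_text(
            "\n".join(a.image_id for a in part) + "\n")
        split_counts[name] = {"images": len(part),
                              "annotations": sum(a.count for a in part)}

    manifest = {
        "seed": int(seed),
        "n_images": int(n_images),
        "config": asdict(cfg),
        "config_digest": cfg.digest(),
        "split_ratios": list(split_ratios),
        "splits": split_counts,
        "total_annotations": int(sum(a.count for a in anns)),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def load_dataset(root, split: str | None = None) -> list[tuple[np.ndarray, AnnotationSet]]:
    """Read back a generated dataset (labelme dialect), optionally one split."""
    from .annotations import read_annotations

    root = Path(root)
    anns = read_annotations(root / "labelme", "labelme")
    if split is not None:
        keep = set((root / f"{split}.txt").read_text().split())
        anns = [a for a in anns if a.image_id in keep]
    out = []
    for a in anns:
        with Image.open(root / "images" / f"{a.image_id}.png") as im:
            out.append((np.asarray(im.convert("RGB")), a))
    return out
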