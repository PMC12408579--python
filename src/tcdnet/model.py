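"""TCD-Net assembly and profiling.

The network is fully convolutional: backbone (PartialNeXt) → optional hybrid
attention per level → feature pyramid → four 1×1 heads, each reduced to one
channel, bilinearly upsampled to the input size and merged (summed by
default) into a single logit map; a sigmoid turns the logits into a
per-pixel probability of an object.

``profile`` reports trainable-parameter and multiply-accumulate counts; one
MAC is reported as one FLOP, and only convolution/linear MACs are counted.
The three architecture switches (PConv, HA, AFM) span the eight ablation
configurations of the design study.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from .attention import HAConfig, HybridAttention
from .backbone import LEVELS, BackboneConfig, PartialNeXt
from .fpn import FeaturePyramid, FPNConfig
from .nn import Conv2d, Module


@dataclass
class ModelConfig:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    ha: HAConfig = field(default_factory=HAConfig)
    fpn: FPNConfig = field(default_factory=FPNConfig)
    merge: str = "sum"              # how per-level logit maps combine: sum | mean
    input_size: tuple[int, int] = (1280, 1280)

    @staticmethod
    def desk_scale(**overrides) -> "ModelConfig":
        """A width/depth-reduced configuration for CPU-scale experiments."""
        cfg = ModelConfig(
            backbone=BackboneConfig(depths=(2, 2, 4, 2), dims=(40, 80, 160, 320)),
            fpn=FPNConfig(channels=128, afm_hidden=32),
            input_size=(256, 256),
        )
        return replace(cfg, **overrides)


@dataclass
class ProbabilityMap:
    """Per-pixel object probability: ``values = sigmoid(logits)``.

    ``logits_tensor`` is kept when produced by the network so losses can
    differentiate through it; ``from_values`` builds one from plain
    probabilities for loss evaluation outside training.
    """

    logits: np.ndarray
    logits_tensor: Tensor | None = None

    @property
    def values(self) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.logits.astype(np.float64)))

    @staticmethod
    def from_values(values: np.ndarray, eps: float = 1e-7) -> "ProbabilityMap":
        p = np.clip(np.asarray(values, dtype=np.float64), eps, 1.0 - eps)
        return ProbabilityMap(np.log(p / (1.0 - p)))


class TCDNet(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | int = 0):
        if isinstance(rng, int):
            rng = np.random.default_rng(rng)
        if cfg.merge not in ("sum", "mean"):
            raise ValueError(f"unknown merge rule {cfg.merge!r}")
        self.cfg = cfg
        self.backbone = PartialNeXt(cfg.backbone, rng)
        if cfg.ha.enabled:
            self.attention = [HybridAttention(ls, rng, cfg.ha.k1d, cfg.ha.k2d)
                              for ls in cfg.ha.local_sizes]
        else:
            self.attention = []
        self.fpn = FeaturePyramid(self.backbone.out_channels(), cfg.fpn, rng)
        self.heads = [Conv2d(cfg.fpn.channels, 1, 1, rng) for _ in LEVELS]

    # forward ----------------------------------------------------------

    def forward_logits(self, image: Tensor) -> Tensor:
        """(3, H, W) image → (H, W) logit map (pre-sigmoid)."""
        _, h, w = image.shape
        feats = self.backbone(image)
        if self.cfg.ha.enabled:
            feats = {lv: att(feats[lv]) for lv, att in zip(LEVELS, self.attention)}
        pyramid = self.fpn(feats)
        maps = []
        for lv, head in zip(("P2", "P3", "P4", "P5"), self.heads):
            maps.append(T.bilinear_resize(head(pyramid[lv]), h, w))
        merged = maps[0]
        for m in maps[1:]:
            merged = merged + m
        if self.cfg.merge == "mean":
            merged = merged * (1.0 / len(maps))
        return T.reshape(merged, (h, w))

    def __call__(self, image) -> ProbabilityMap:
        if not isinstance(image, Tensor):
            image = Tensor(image)
        logits = self.forward_logits(image)
        return ProbabilityMap(logits.data.copy(), logits_tensor=logits)

    # profiling --------------------------------------------------------

    def macs(self, h: int | None = None, w: int | None = None) -> int:
        if h is None:
            h, w = self.cfg.input_size
        if h % 32 or w % 32:
            raise ValueError("profile input size must be divisible by 32")
        total = self.backbone.macs(h, w)
        if self.cfg.ha.enabled:
            for att, lv, c in zip(self.attention, LEVELS, self.cfg.backbone.dims):
                s = {"C2": 4, "C3": 8, "C4": 16, "C5": 32}[lv]
                total += att.macs(h // s, w // s, c)
        total += self.fpn.macs(h, w)
        for head, s in zip(self.heads, (4, 8, 16, 32)):
            total += head.macs(h // s, w // s)
        return total

    # checkpointing ----------------------------------------------------

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict(dict(data))


def profile(cfg: ModelConfig, input_size: tuple[int, int] | None = None) -> dict:
    """Parameter and MAC counts of one configuration.

    Returns ``{"params": int, "macs": int}`` with MACs evaluated at
    ``input_size`` (default: the config's input size).
    """
    model = TCDNet(cfg, rng=np.random.default_rng(0))
    h, w = input_size or cfg.input_size
    return {"params": model.n_params(), "macs": model.macs(h, w)}


def ablation_grid(base: ModelConfig | None = None,
                  input_size: tuple[int, int] | None = None) -> list[dict]:
    """Profile the eight PConv × HA × AFM ablation rows."""
    base = base or ModelConfig()
    rows = []
    for pconv in (False, True):
        for ha_on in (False, True):
            for afm in (False, True):
                cfg = replace(
                    base,
                    backbone=replace(base.backbone, use_pconv=pconv),
                    ha=replace(base.ha, enabled=ha_on),
                    fpn=replace(base.fpn, afm_enabled=afm),
                )
                stats = profile(cfg, input_size)
                rows.append({"pconv": pconv, "ha": ha_on, "afm": afm, **stats})
    return rows
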