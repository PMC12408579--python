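"""Top-down feature pyramid with adaptive feature mixing.

Lateral 1×1 convolutions bring C2–C5 to a common width (256 by default);
the top level P5 is the C5 lateral, and every lower level fuses its lateral
with the 2× upsampled level above.  With AFM enabled the fusion is a learned
per-element convex combination

    AFM(f1, f2) = f1 * W + f2 * (1 - W)

where W = sigmoid(spatial(f1+f2) + channel(f1+f2)): the spatial branch is a
1×1 bottleneck conv pair, the channel branch a global-pooled two-layer FFN
broadcast over space.  With AFM disabled the fusion is plain element-wise
addition (vanilla FPN, lateral-only — no 3×3 smoothing convolutions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from .backbone import LEVELS
from .nn import Conv2d, Linear, Module


@dataclass
class FPNConfig:
    channels: int = 256
    afm_enabled: bool = True
    afm_hidden: int = 64


class AdaptiveFeatureMixer(Module):
    def __init__(self, d: int, hidden: int, rng: np.random.Generator):
        self.d = d
        self.sp1 = Conv2d(d, hidden, 1, rng)
        self.sp2 = Conv2d(hidden, d, 1, rng)
        self.ch1 = Linear(d, hidden, rng)
        self.ch2 = Linear(hidden, d, rng)

    def weight(self, f1: Tensor, f2: Tensor) -> Tensor:
        """The fusion weight W, a (d, h, w) tensor with entries in (0, 1)."""
        if f1.shape != f2.shape:
            raise ValueError(f"AFM inputs differ in shape: {f1.shape} vs {f2.shape}")
        s = f1 + f2
        spatial = self.sp2(T.relu(self.sp1(s)))
        channel = self.ch2(T.relu(self.ch1(T.global_avg_pool(s))))
        return T.sigmoid(spatial + T.reshape(channel, (self.d, 1, 1)))

    def __call__(self, f1: Tensor, f2: Tensor) -> Tensor:
        w = self.weight(f1, f2)
        return T.mul(f1, w) + T.mul(f2, 1.0 - w)

    def macs(self, h: int, w: int) -> int:
        return (self.sp1.macs(h, w) + self.sp2.macs(h, w)
                + self.ch1.macs() + self.ch2.macs())


class FeaturePyramid(Module):
    """C2..C5 → P2..P5, all at ``cfg.channels`` channels."""

    def __init__(self, in_channels: dict[str, int], cfg: FPNConfig,
                 rng: np.random.Generator):
        self.cfg = cfg
        self.laterals = [Conv2d(in_channels[lv], cfg.channels, 1, rng) for lv in LEVELS]
        if cfg.afm_enabled:
            # one mixer per merge point: P4, P3, P2
            self.mixers = [AdaptiveFeatureMixer(cfg.channels, cfg.afm_hidden, rng)
                           for _ in range(3)]
        else:
            self.mixers = []

    def __call__(self, feats: dict[str, Tensor]) -> dict[str, Tensor]:
        lats = {lv: conv(feats[lv]) for lv, conv in zip(LEVELS, self.laterals)}
        out: dict[str, Tensor] = {"P5": lats["C5"]}
        for i, (hi, lo) in enumerate([("P5", "C4"), ("P4", "C3"), ("P3", "C2")]):
            lat = lats[lo]
            _, h, w = lat.shape
            up = T.bilinear_resize(out[hi], h, w)
            if self.cfg.afm_enabled:
                fused = self.mixers[i](lat, up)
            else:
                fused = lat + up
            out["P" + lo[1]] = fused
        return out

    def macs(self, h: int, w: int) -> int:
        """MACs at backbone input size (h, w); C2..C5 sit at strides 4..32."""
        total = 0
        for lv, conv in zip(LEVELS, self.laterals):
            s = {"C2": 4, "C3": 8, "C4": 16, "C5": 32}[lv]
            total += conv.macs(h // s, w // s)
        for mixer, s in zip(self.mixers, (16, 8, 4)):
            total += mixer.macs(h // s, w // s)
        return total
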