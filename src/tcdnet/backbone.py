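"""PartialNeXt: a hierarchical convolutional backbone built from
ConvNeXtV2-style blocks whose 7×7 depthwise convolution is replaced by a
partial convolution (dense 7×7 over a quarter of the channels, the rest
passed through).

Four stages produce feature maps C2–C5 at strides 4/8/16/32 with channel
widths taken from the Nano configuration (80/160/320/640) by default.  With
``use_pconv=False`` the blocks revert to the depthwise convolution, giving
the ConvNeXtV2-Nano baseline used for ablation accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from .nn import Conv2d, DepthwiseConv2d, GRN, LayerNorm, Module, PartialConv2d

LEVELS = ("C2", "C3", "C4", "C5")
STRIDES = {"C2": 4, "C3": 8, "C4": 16, "C5": 32}


@dataclass
class BackboneConfig:
    depths: tuple[int, ...] = (2, 2, 8, 2)
    dims: tuple[int, ...] = (80, 160, 320, 640)
    pconv_ratio: float = 0.25
    kernel_size: int = 7
    use_pconv: bool = True


class Block(Module):
    """Residual block: PConv/DWConv 7×7 → LN → 1×1 expand 4c → GELU → GRN →
    1×1 project → + input."""

    def __init__(self, c: int, cfg: BackboneConfig, rng: np.random.Generator):
        if cfg.use_pconv:
            self.spatial = PartialConv2d(c, cfg.kernel_size, rng, ratio=cfg.pconv_ratio)
        else:
            self.spatial = DepthwiseConv2d(c, cfg.kernel_size, rng)
        self.norm = LayerNorm(c)
        self.fc1 = Conv2d(c, 4 * c, 1, rng)
        self.grn = GRN(4 * c)
        self.fc2 = Conv2d(4 * c, c, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        y = self.spatial(x)
        y = self.norm(y)
        y = self.fc1(y)
        y = T.gelu(y)
        y = self.grn(y)
        y = self.fc2(y)
        return y + x

    def macs(self, h: int, w: int) -> int:
        return self.spatial.macs(h, w) + self.fc1.macs(h, w) + self.fc2.macs(h, w)


class Downsample(Module):
    """LayerNorm then 2×2 stride-2 convolution doubling the channel count."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.norm = LayerNorm(cin)
        self.conv = Conv2d(cin, cout, 2, rng, stride=2, padding=0)

    def __call__(self, x: Tensor) -> Tensor:
        c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"downsample needs even spatial size, got {h}x{w}")
        return self.conv(self.norm(x))

    def macs(self, h: int, w: int) -> int:
        return self.conv.macs(h, w)


class Stem(Module):
    """4×4 stride-4 convolution + LayerNorm (the ConvNeXt patchify stem)."""

    def __init__(self, cout: int, rng: np.random.Generator):
        self.conv = Conv2d(3, cout, 4, rng, stride=4, padding=0)
        self.norm = LayerNorm(cout)

    def __call__(self, x: Tensor) -> Tensor:
        return self.norm(self.conv(x))

    def macs(self, h: int, w: int) -> int:
        return self.conv.macs(h, w)


class PartialNeXt(Module):
    """The full backbone; ``__call__`` maps a 3×H×W image to {C2..C5}."""

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.stem = Stem(cfg.dims[0], rng)
        self.downsamples = [Downsample(cfg.dims[i - 1], cfg.dims[i], rng)
                            for i in range(1, 4)]
        self.stages = [[Block(cfg.dims[i], cfg, rng) for _ in range(cfg.depths[i])]
                       for i in range(4)]

    def __call__(self, image: Tensor) -> dict[str, Tensor]:
        c, h, w = image.shape
        if c != 3:
            raise ValueError(f"expected a 3-channel image, got {c} channels")
        if h % 32 or w % 32:
            raise ValueError(
                f"image size {h}x{w} not divisible by 32; pad the image first")
        feats: dict[str, Tensor] = {}
        x = self.stem(image)
        for i, level in enumerate(LEVELS):
            if i > 0:
                x = self.downsamples[i - 1](x)
            for block in self.stages[i]:
                x = block(x)
            feats[level] = x
        return feats

    def out_channels(self) -> dict[str, int]:
        return dict(zip(LEVELS, self.cfg.dims))

    def macs(self, h: int, w: int) -> int:
        total = self.stem.macs(h, w)
        sh, sw = h // 4, w // 4
        for i in range(4):
            if i > 0:
                total += self.downsamples[i - 1].macs(sh, sw)
                sh, sw = sh // 2, sw // 2
            for block in self.stages[i]:
                total += block.macs(sh, sw)
        return total
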