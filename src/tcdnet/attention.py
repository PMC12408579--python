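"""Hybrid attention: mixed local/global channel attention followed by CBAM
spatial attention, with a residual connection:

    HA(f) = SA(CA(f)) + f

The channel attention pools the feature map to a small ls×ls grid (local
branch) and further to 1×1 (global branch), runs a weight-shared 3-tap 1-D
convolution along the channel axis of both, adds the broadcast global result
to the local one, resizes to the input size, and gates the input through a
sigmoid.  The spatial attention gates by a 3×3 convolution over the per-pixel
channel mean and max.  One HA instance costs 23 parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from .nn import Conv2d, Module, trunc_normal


@dataclass
class HAConfig:
    enabled: bool = True
    local_sizes: tuple[int, ...] = (32, 16, 8, 4)   # for C2..C5
    k1d: int = 3
    k2d: int = 3


class ChannelAttention(Module):
    """Mixed local/global channel attention with a shared 1-D convolution."""

    def __init__(self, ls: int, rng: np.random.Generator, k1d: int = 3):
        self.ls = ls
        self.w1d = Tensor(trunc_normal(rng, (k1d,)), requires_grad=True)
        self.b1d = Tensor(np.zeros((), np.float32), requires_grad=True)

    def __call__(self, f: Tensor) -> Tensor:
        c, h, w = f.shape
        ls = self.ls
        if ls > min(h, w):
            warnings.warn(f"local size {ls} exceeds feature map {h}x{w}; clamping")
            ls = min(h, w)
        local = T.adaptive_avg_pool(f, ls, ls)
        glob = T.adaptive_avg_pool(local, 1, 1)
        local_att = T.conv1d_channels(local, self.w1d, self.b1d)
        glob_att = T.conv1d_channels(glob, self.w1d, self.b1d)
        fused = local_att + T.bilinear_resize(glob_att, ls, ls)
        gate = T.sigmoid(T.bilinear_resize(fused, h, w))
        return T.mul(f, gate)

    def macs(self, h: int, w: int, c: int) -> int:
        ls = min(self.ls, h, w)
        return 3 * c * ls * ls + 3 * c


class SpatialAttention(Module):
    """CBAM spatial attention: [channel-mean, channel-max] → k×k conv → sigmoid."""

    def __init__(self, rng: np.random.Generator, k2d: int = 3):
        self.conv = Conv2d(2, 1, k2d, rng)

    def __call__(self, f: Tensor) -> Tensor:
        stats = T.channel_mean_max(f)
        gate = T.sigmoid(self.conv(stats))
        return T.mul(f, gate)

    def macs(self, h: int, w: int) -> int:
        return self.conv.macs(h, w)


class HybridAttention(Module):
    def __init__(self, ls: int, rng: np.random.Generator, k1d: int = 3, k2d: int = 3):
        self.channel = ChannelAttention(ls, rng, k1d)
        self.spatial = SpatialAttention(rng, k2d)

    def __call__(self, f: Tensor) -> Tensor:
        return self.spatial(self.channel(f)) + f

    def macs(self, h: int, w: int, c: int) -> int:
        return self.channel.macs(h, w, c) + self.spatial.macs(h, w)
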