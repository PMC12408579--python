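"""Neural-network layers, parameter management and the Adam optimizer.

Layers wrap the autodiff primitives in :mod:`tcdnet._tensor` and additionally
expose analytic multiply-accumulate (MAC) counts so the model can be profiled
without running a forward pass at full resolution.  MACs are counted for
convolutions and linear layers only — normalisation, activations, pooling and
interpolation are excluded, the convention under which efficiency tables in
the ConvNeXt literature are reported.
"""

from __future__ import annotations

import numpy as np

from . import _tensor as T
from ._tensor import Tensor


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) truncated at ±2 std, the ConvNeXt weight init."""
    w = rng.normal(0.0, std, size=shape)
    return np.clip(w, -2 * std, 2 * std).astype(np.float32)


class Module:
    """Base class; children registered as attributes are discovered recursively."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params: list[Tensor], seen: set[int]) -> None:
        for value in vars(self).values():
            self._collect_value(value, params, seen)

    @staticmethod
    def _collect_value(value, params, seen):
        if isinstance(value, Tensor) and value.requires_grad:
            if id(value) not in seen:
                seen.add(id(value))
                params.append(value)
        elif isinstance(value, Module):
            value._collect(params, seen)
        elif isinstance(value, (list, tuple)):
            for v in value:
                Module._collect_value(v, params, seen)

    def n_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # state dict -------------------------------------------------------

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        seen: set[int] = set()
        self._collect_named(prefix, out, seen)
        return out

    def _collect_named(self, prefix, out, seen):
        for name, value in vars(self).items():
            self._named_value(f"{prefix}{name}", value, out, seen)

    @staticmethod
    def _named_value(path, value, out, seen):
        if isinstance(value, Tensor) and value.requires_grad:
            if id(value) not in seen:
                seen.add(id(value))
                out.append((path, value))
        elif isinstance(value, Module):
            value._collect_named(path + ".", out, seen)
        elif isinstance(value, (list, tuple)):
            for i, v in enumerate(value):
                Module._named_value(f"{path}.{i}", v, out, seen)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def macs(self, h: int, w: int) -> int:
        """MACs of one forward pass at input spatial size (h, w)."""
        return 0


class Conv2d(Module):
    """Dense convolution on (Cin, H, W); same-padding by default when k is odd."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None, bias: bool = True):
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.padding = (k // 2 if stride == 1 else 0) if padding is None else padding
        self.weight = Tensor(trunc_normal(rng, (cout, cin, k, k)), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)

    def out_size(self, h: int, w: int) -> tuple[int, int]:
        s, p, k = self.stride, self.padding, self.k
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def macs(self, h: int, w: int) -> int:
        ho, wo = self.out_size(h, w)
        return self.k * self.k * self.cin * self.cout * ho * wo


class DepthwiseConv2d(Module):
    def __init__(self, c: int, k: int, rng: np.random.Generator, bias: bool = True):
        self.c, self.k = c, k
        self.weight = Tensor(trunc_normal(rng, (c, k, k)), requires_grad=True)
        self.bias = Tensor(np.zeros(c, np.float32), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return T.depthwise_conv2d(x, self.weight, self.bias, padding=self.k // 2)

    def macs(self, h: int, w: int) -> int:
        return self.k * self.k * self.c * h * w


class PartialConv2d(Module):
    """Partial convolution: a dense k×k conv over the first ``c * ratio``
    channels, the remaining channels passed through untouched.

    The output is exactly the composition slice → dense conv → concatenate.
    """

    def __init__(self, c: int, k: int, rng: np.random.Generator, ratio: float = 0.25):
        n_conv = c * ratio
        if abs(n_conv - round(n_conv)) > 1e-9:
            raise ValueError(f"channel count {c} not divisible by 1/ratio={1/ratio:g}")
        self.c = c
        self.n_conv = int(round(n_conv))
        self.conv = Conv2d(self.n_conv, self.n_conv, k, rng, bias=True)

    def __call__(self, x: Tensor) -> Tensor:
        if self.n_conv == self.c:
            return self.conv(x)
        head = self.conv(x[: self.n_conv])
        return T.concat([head, x[self.n_conv:]], axis=0)

    def macs(self, h: int, w: int) -> int:
        return self.conv.macs(h, w)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, bias: bool = True):
        self.cin, self.cout = cin, cout
        self.weight = Tensor(trunc_normal(rng, (cout, cin)), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return T.linear(x, self.weight, self.bias)

    def macs(self, h: int = 1, w: int = 1) -> int:
        return self.cin * self.cout


class LayerNorm(Module):
    """Channel-wise LayerNorm at every spatial position (channels-first input)."""

    def __init__(self, c: int):
        self.gamma = Tensor(np.ones(c, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return T.layer_norm_channels(x, self.gamma, self.beta)


class GRN(Module):
    """Global response normalisation; gamma/beta start at zero (identity)."""

    def __init__(self, c: int):
        self.gamma = Tensor(np.zeros(c, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return T.grn(x, self.gamma, self.beta)


class Adam:
    """Adam with L2 weight decay added to the gradient (torch.optim.Adam style)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-4):
        self.params = params
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
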