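"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The package trains a fully convolutional network with batch size 1, so every
operation here works on unbatched arrays: feature maps are ``(C, H, W)``,
vectors are ``(C,)``.  The engine is tape-based: each :class:`Tensor` records
its parents and a closure that accumulates gradients into them; ``backward``
runs the closures in reverse topological order.

Only the operations the network needs are implemented, and the hot ones
(convolution, layer normalisation, separable spatial resampling) have fused
hand-written backward passes.  Everything is float32.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

_F32 = np.float32

_INV_SQRT2 = _F32(0.7071067811865476)
_INV_SQRT_2PI = _F32(0.3989422804014327)


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=_F32)
    return a


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- bookkeeping ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=_F32)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without an explicit gradient needs a scalar")
            grad = np.ones_like(self.data)
        self.grad = _as_array(grad)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- python protocol -----------------------------------------------

    def item(self) -> float:
        return float(self.data)

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul_scalar(self, -1.0)

    def __sub__(self, other):
        return add(self, -_ensure(other))

    def __rsub__(self, other):
        return add(_ensure(other), -self)

    def __mul__(self, other):
        if np.isscalar(other):
            return mul_scalar(self, float(other))
        return mul(self, other)

    __rmul__ = __mul__

    def __getitem__(self, idx):
        return getitem(self, idx)


def _ensure(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / reduction primitives
# ---------------------------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def mul(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    out_data = a.data * b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def mul_scalar(a: Tensor, s: float) -> Tensor:
    s = _F32(s)

    def bwd(g):
        a._accum(g * s)

    return Tensor(a.data * s, parents=(a,), backward=bwd)


def tsum(a: Tensor) -> Tensor:
    def bwd(g):
        a._accum(np.full_like(a.data, g))

    return Tensor(a.data.sum(), parents=(a,), backward=bwd)


def tmean(a: Tensor) -> Tensor:
    n = a.data.size

    def bwd(g):
        a._accum(np.full_like(a.data, g / n))

    return Tensor(a.data.mean(), parents=(a,), backward=bwd)


def getitem(a: Tensor, idx) -> Tensor:
    out_data = a.data[idx]

    def bwd(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        a._accum(full)

    return Tensor(out_data, parents=(a,), backward=bwd)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_ensure(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor(out_data, parents=tuple(tensors), backward=bwd)


def reshape(a: Tensor, shape) -> Tensor:
    def bwd(g):
        a._accum(g.reshape(a.data.shape))

    return Tensor(a.data.reshape(shape), parents=(a,), backward=bwd)


# ---------------------------------------------------------------------------
# nonlinearities
# ---------------------------------------------------------------------------


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data.astype(np.float64)))
    s = s.astype(_F32)

    def bwd(g):
        a._accum(g * s * (1.0 - s))

    return Tensor(s, parents=(a,), backward=bwd)


def relu(a: Tensor) -> Tensor:
    out_data = np.maximum(a.data, 0)

    def bwd(g):
        a._accum(g * (a.data > 0))

    return Tensor(out_data, parents=(a,), backward=bwd)


def gelu(a: Tensor) -> Tensor:
    """Exact (erf-based) GELU."""
    x = a.data
    cdf = 0.5 * (1.0 + erf(x * _INV_SQRT2)).astype(_F32)
    out_data = x * cdf

    def bwd(g):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
        a._accum(g * (cdf + x * pdf))

    return Tensor(out_data, parents=(a,), backward=bwd)


def softplus(a: Tensor) -> Tensor:
    """log(1 + exp(x)), numerically stable; d/dx = sigmoid(x)."""
    out_data = np.logaddexp(0.0, a.data.astype(np.float64)).astype(_F32)

    def bwd(g):
        s = 1.0 / (1.0 + np.exp(-a.data.astype(np.float64)))
        a._accum(g * s.astype(_F32))

    return Tensor(out_data, parents=(a,), backward=bwd)


# ---------------------------------------------------------------------------
# linear algebra / convolution
# ---------------------------------------------------------------------------


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """w @ x (+ b) for a vector x of shape (Cin,); w is (Cout, Cin)."""
    out_data = w.data @ x.data
    if b is not None:
        out_data = out_data + b.data

    def bwd(g):
        if w.requires_grad:
            w._accum(np.outer(g, x.data))
        if x.requires_grad:
            x._accum(w.data.T @ g)
        if b is not None and b.requires_grad:
            b._accum(g)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents=parents, backward=bwd)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """Dense 2-D convolution (cross-correlation) on a (Cin, H, W) map.

    ``w`` is (Cout, Cin, kh, kw).  1x1/stride-1 convolutions take a pure
    matmul fast path; the general case uses im2col + GEMM.
    """
    cin, h, wdt = x.data.shape
    cout, cin_w, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d: input has {cin} channels, weight expects {cin_w}")

    if kh == 1 and kw == 1 and stride == 1 and padding == 0:
        wm = w.data.reshape(cout, cin)
        out2 = wm @ x.data.reshape(cin, h * wdt)
        if b is not None:
            out2 = out2 + b.data[:, None]
        out_data = out2.reshape(cout, h, wdt)

        def bwd(g):
            g2 = g.reshape(cout, h * wdt)
            if w.requires_grad:
                w._accum((g2 @ x.data.reshape(cin, h * wdt).T).reshape(w.data.shape))
            if x.requires_grad:
                x._accum((wm.T @ g2).reshape(x.data.shape))
            if b is not None and b.requires_grad:
                b._accum(g2.sum(axis=1))

        parents = (x, w) if b is None else (x, w, b)
        return Tensor(out_data, parents=parents, backward=bwd)

    s, p = stride, padding
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p))) if p else x.data
    hp, wp = xp.shape[1], xp.shape[2]
    ho = (hp - kh) // s + 1
    wo = (wp - kw) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    win = win[:, ::s, ::s]                                   # (Cin, Ho, Wo, kh, kw)
    cols = win.transpose(0, 3, 4, 1, 2).reshape(cin * kh * kw, ho * wo)
    cols = np.ascontiguousarray(cols)
    wm = w.data.reshape(cout, cin * kh * kw)
    out2 = wm @ cols
    if b is not None:
        out2 = out2 + b.data[:, None]
    out_data = out2.reshape(cout, ho, wo)

    def bwd(g):
        g2 = g.reshape(cout, ho * wo)
        if w.requires_grad:
            w._accum((g2 @ cols.T).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g2.sum(axis=1))
        if x.requires_grad:
            dcols = (wm.T @ g2).reshape(cin, kh, kw, ho, wo)
            dxp = np.zeros((cin, hp, wp), dtype=_F32)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, i:i + s * ho:s, j:j + s * wo:s] += dcols[:, i, j]
            x._accum(dxp[:, p:hp - p, p:wp - p] if p else dxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents=parents, backward=bwd)


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     padding: int = 0) -> Tensor:
    """Depthwise k×k convolution, one filter per channel; w is (C, kh, kw)."""
    c, h, wdt = x.data.shape
    _, kh, kw = w.data.shape
    p = padding
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p))) if p else x.data
    ho = xp.shape[1] - kh + 1
    wo = xp.shape[2] - kw + 1
    out_data = np.zeros((c, ho, wo), dtype=_F32)
    for i in range(kh):
        for j in range(kw):
            out_data += w.data[:, i, j, None, None] * xp[:, i:i + ho, j:j + wo]
    if b is not None:
        out_data += b.data[:, None, None]

    def bwd(g):
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    dw[:, i, j] = (g * xp[:, i:i + ho, j:j + wo]).sum(axis=(1, 2))
            w._accum(dw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(1, 2)))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, i:i + ho, j:j + wo] += w.data[:, i, j, None, None] * g
            x._accum(dxp[:, p:xp.shape[1] - p, p:xp.shape[2] - p] if p else dxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents=parents, backward=bwd)


def conv1d_channels(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """1-D convolution along the channel axis of a (C, ...) tensor.

    The channel axis is treated as the sequence (ECA-style attention); the
    same 3-tap kernel is shared across all remaining positions.  ``w`` has
    shape (k,) with odd k, ``b`` is a scalar tensor, zero padding.
    """
    k = w.data.shape[0]
    p = k // 2
    c = x.data.shape[0]
    pad_width = [(p, p)] + [(0, 0)] * (x.data.ndim - 1)
    xp = np.pad(x.data, pad_width)
    out_data = np.zeros_like(x.data)
    for i in range(k):
        out_data += w.data[i] * xp[i:i + c]
    out_data += b.data

    def bwd(g):
        if w.requires_grad:
            dw = np.array([(g * xp[i:i + c]).sum() for i in range(k)], dtype=_F32)
            w._accum(dw)
        if b.requires_grad:
            b._accum(np.asarray(g.sum(), dtype=_F32))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(k):
                dxp[i:i + c] += w.data[i] * g
            x._accum(dxp[p:p + c])

    return Tensor(out_data, parents=(x, w, b), backward=bwd)


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

_LN_EPS = 1e-6


def layer_norm_channels(x: Tensor, gamma: Tensor, beta: Tensor) -> Tensor:
    """LayerNorm over the channel axis at every spatial position.

    ``x`` is (C, H, W) (or (C,)); normalisation is over axis 0, affine
    parameters are per-channel.  Epsilon 1e-6, the ConvNeXt convention.
    """
    xd = x.data
    mu = xd.mean(axis=0)
    var = xd.var(axis=0)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (xd - mu) * inv
    gshape = (-1,) + (1,) * (xd.ndim - 1)
    out_data = gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape)

    def bwd(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).reshape(xd.shape[0], -1).sum(axis=1))
        if beta.requires_grad:
            beta._accum(g.reshape(xd.shape[0], -1).sum(axis=1))
        if x.requires_grad:
            dxhat = g * gamma.data.reshape(gshape)
            m1 = dxhat.mean(axis=0)
            m2 = (dxhat * xhat).mean(axis=0)
            x._accum(inv * (dxhat - m1 - xhat * m2))

    return Tensor(out_data, parents=(x, gamma, beta), backward=bwd)


_GRN_EPS = 1e-6


def grn(x: Tensor, gamma: Tensor, beta: Tensor) -> Tensor:
    """Global response normalisation (ConvNeXtV2) on a (C, H, W) map.

    Per channel c: G_c = ||x_c||_2 over space, N_c = G_c / (mean_c G + eps),
    out = gamma * (x * N) + beta + x.  gamma/beta start at zero so the layer
    is initially the identity.
    """
    xd = x.data
    c = xd.shape[0]
    gx = np.sqrt((xd ** 2).sum(axis=(1, 2)))                  # (C,)
    m = gx.mean() + _GRN_EPS
    nx = gx / m                                               # (C,)
    out_data = gamma.data[:, None, None] * (xd * nx[:, None, None]) \
        + beta.data[:, None, None] + xd

    def bwd(g):
        if gamma.requires_grad:
            gamma._accum((g * xd * nx[:, None, None]).sum(axis=(1, 2)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(1, 2)))
        if x.requires_grad:
            dn = (g * gamma.data[:, None, None] * xd).sum(axis=(1, 2))   # dL/dN_c
            dgx = dn / m - (dn @ gx) / (m * m * c)                        # dL/dG_c
            safe = np.where(gx > 0, gx, 1.0)
            dx = g * (1.0 + gamma.data[:, None, None] * nx[:, None, None]) \
                + (dgx / safe)[:, None, None] * xd
            x._accum(dx.astype(_F32))

    return Tensor(out_data, parents=(x, gamma, beta), backward=bwd)


# ---------------------------------------------------------------------------
# separable spatial resampling (bilinear resize / adaptive average pooling)
# ---------------------------------------------------------------------------


def _bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic (n_out, n_in) bilinear interpolation matrix.

    Sample positions follow the half-pixel (align_corners=False) convention.
    """
    m = np.zeros((n_out, n_in), dtype=_F32)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = (src - lo).astype(_F32)
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


def _avgpool_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Adaptive average-pooling matrix: bin i covers [floor(i*n/s), ceil((i+1)*n/s))."""
    m = np.zeros((n_out, n_in), dtype=_F32)
    for i in range(n_out):
        lo = (i * n_in) // n_out
        hi = -(-((i + 1) * n_in) // n_out)   # ceil
        m[i, lo:hi] = 1.0 / (hi - lo)
    return m


_MATRIX_CACHE: dict = {}


def _cached(kind: str, n_out: int, n_in: int) -> np.ndarray:
    key = (kind, n_out, n_in)
    m = _MATRIX_CACHE.get(key)
    if m is None:
        m = _bilinear_matrix(n_out, n_in) if kind == "bilinear" else _avgpool_matrix(n_out, n_in)
        _MATRIX_CACHE[key] = m
    return m


def _lincomb2d(x: Tensor, ry: np.ndarray, rx: np.ndarray) -> Tensor:
    """out[c] = ry @ x[c] @ rx.T — shared machinery for resize and pooling."""
    out_data = np.matmul(np.matmul(ry, x.data), rx.T)

    def bwd(g):
        x._accum(np.matmul(np.matmul(ry.T, g), rx))

    return Tensor(out_data, parents=(x,), backward=bwd)


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resampling of a (C, H, W) map (half-pixel convention)."""
    c, h, w = x.data.shape
    if (h, w) == (out_h, out_w):
        return x
    return _lincomb2d(x, _cached("bilinear", out_h, h), _cached("bilinear", out_w, w))


def adaptive_avg_pool(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Adaptive average pooling of a (C, H, W) map to (C, out_h, out_w)."""
    c, h, w = x.data.shape
    return _lincomb2d(x, _cached("avg", out_h, h), _cached("avg", out_w, w))


def global_avg_pool(x: Tensor) -> Tensor:
    """(C, H, W) → (C,) spatial mean."""
    c, h, w = x.data.shape
    n = h * w

    def bwd(g):
        x._accum(np.broadcast_to(g[:, None, None] / n, x.data.shape))

    return Tensor(x.data.mean(axis=(1, 2)), parents=(x,), backward=bwd)


def channel_mean_max(x: Tensor) -> Tensor:
    """Stack the per-pixel channel mean and channel max into a (2, H, W) map."""
    xd = x.data
    c = xd.shape[0]
    am = xd.argmax(axis=0)
    mx = np.take_along_axis(xd, am[None], axis=0)[0]
    out_data = np.stack([xd.mean(axis=0), mx])

    def bwd(g):
        dx = np.broadcast_to(g[0] / c, xd.shape).copy()
        hh, ww = np.indices(am.shape)
        dx[am, hh, ww] += g[1]
        x._accum(dx)

    return Tensor(out_data, parents=(x,), backward=bwd)
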