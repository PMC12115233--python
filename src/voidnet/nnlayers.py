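"""Neural-network layers on the autodiff engine.

Layers follow the NCHW layout.  Convolutions are computed by im2col +
matmul; the im2col patch matrix is cached on the tape for the backward
pass, which is cheap at the feature-map sizes this detector runs at.

Initialisation is fully seeded: every layer takes a ``numpy.random.Generator``
and draws from it in construction order, so a model built twice from the same
seed has bit-identical parameters.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autodiff import Tensor, silu

__all__ = [
    "Module",
    "ModuleList",
    "Conv2d",
    "DWConv2d",
    "BatchNorm2d",
    "LayerNorm",
    "Linear",
    "ConvBnAct",
    "conv2d",
    "dwconv2d",
    "upsample2x",
    "AdamW",
]

_DTYPE = np.float32


# --------------------------------------------------------------- module base

class Module:
    """Minimal container: auto-registers sub-modules and parameter tensors."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_mods", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._mods[name] = value
        object.__setattr__(self, name, value)

    # iteration ------------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for n, p in self._params.items():
            yield prefix + n, p
        for n, m in self._mods.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for n in getattr(self, "_buffer_names", ()):
            yield prefix + n, getattr(self, n)
        for n, m in self._mods.items():
            yield from m.named_buffers(prefix + n + ".")

    # mode -----------------------------------------------------------------
    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._mods.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # state ----------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        d = {n: p.data.copy() for n, p in self.named_parameters()}
        d.update({"buffer:" + n: b.copy() for n, b in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, arr in d.items():
            if name.startswith("buffer:"):
                bname = name[len("buffer:"):]
                *path, leaf = bname.split(".")
                obj = self
                for p in path:
                    obj = obj._mods[p]
                getattr(obj, leaf)[...] = arr
            else:
                if params[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}")
                params[name].data[...] = arr

    def __call__(self, *a, **kw):
        return self.forward(*a, **kw)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        setattr(self, str(len(self._list)), m)
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


# ---------------------------------------------------------- functional convs

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    # win: a (N, C, Ho, Wo, k, k) view into xp — copied only on reshape
    return win, xp.shape


def _col2im(dcols: np.ndarray, xp_shape, k: int, stride: int, pad: int,
            out_h: int, out_w: int) -> np.ndarray:
    # dcols: (N, C, Ho, Wo, k, k) gradients of the sliding windows
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki:ki + stride * out_h:stride,
                kj:kj + stride * out_w:stride] += dcols[:, :, :, :, ki, kj]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """2-D cross-correlation, weight layout (C_out, C_in, k, k)."""
    n, c, h, wd = x.shape
    co, ci, k, _ = w.shape
    if ci != c:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {ci}")
    win, xp_shape = _im2col(x.data, k, stride, pad)
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    wmat = w.data.reshape(co, c * k * k)
    val = (cols @ wmat.T).reshape(n, ho, wo, co).transpose(0, 3, 1, 2)
    if b is not None:
        val = val + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(val, any(p.requires_grad for p in parents), parents)

    def bwd(g):
        gm = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, co)
        if w.requires_grad:
            w._accumulate((gm.T @ cols).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = (gm @ wmat).reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
            x._accumulate(_col2im(dcols, xp_shape, k, stride, pad, ho, wo))

    out._backward = bwd
    return out


def dwconv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
             stride: int = 1, pad: int = 0) -> Tensor:
    """Depthwise convolution: one k×k kernel per channel, layout (C, k, k).

    Computed as k² shifted multiply-adds on the padded input, which is much
    faster than an im2col route for per-channel kernels.
    """
    n, c, h, wd = x.shape
    cw, k, _ = w.shape
    if cw != c:
        raise ValueError(f"dwconv2d: input has {c} channels, weight expects {cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (wd + 2 * pad - k) // stride + 1
    val = np.zeros((n, c, ho, wo), dtype=x.data.dtype)
    for ki in range(k):
        for kj in range(k):
            val += w.data[None, :, ki, kj, None, None] * \
                xp[:, :, ki:ki + stride * ho:stride, kj:kj + stride * wo:stride]
    if b is not None:
        val += b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(val, any(p.requires_grad for p in parents), parents)

    def bwd(g):
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for ki in range(k):
                for kj in range(k):
                    patch = xp[:, :, ki:ki + stride * ho:stride,
                               kj:kj + stride * wo:stride]
                    dw[:, ki, kj] = (g * patch).sum(axis=(0, 2, 3))
            w._accumulate(dw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxp = np.zeros(xp.shape, dtype=g.dtype)
            for ki in range(k):
                for kj in range(k):
                    dxp[:, :, ki:ki + stride * ho:stride,
                        kj:kj + stride * wo:stride] += \
                        w.data[None, :, ki, kj, None, None] * g
            x._accumulate(dxp[:, :, pad:pad + h, pad:pad + wd] if pad
                          else dxp)

    out._backward = bwd
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour ×2 upsampling."""
    n, c, h, w = x.shape
    val = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    out = Tensor(val, x.requires_grad, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    out._backward = bwd
    return out


# --------------------------------------------------------------- layer types

class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = (k // 2) if pad is None else pad
        fan_in = cin * k * k
        bound = math.sqrt(6.0 / fan_in)  # Kaiming-uniform
        self.weight = Tensor(
            rng.uniform(-bound, bound, (cout, cin, k, k)).astype(_DTYPE),
            requires_grad=True)
        self.bias = (Tensor(np.zeros(cout, dtype=_DTYPE), requires_grad=True)
                     if bias else None)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.pad)


class DWConv2d(Module):
    def __init__(self, c: int, k: int = 3, stride: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = k // 2
        bound = math.sqrt(6.0 / (k * k))
        self.weight = Tensor(rng.uniform(-bound, bound, (c, k, k)).astype(_DTYPE),
                             requires_grad=True)
        self.bias = (Tensor(np.zeros(c, dtype=_DTYPE), requires_grad=True)
                     if bias else None)

    def forward(self, x: Tensor) -> Tensor:
        return dwconv2d(x, self.weight, self.bias, self.stride, self.pad)


class BatchNorm2d(Module):
    _buffer_names = ("running_mean", "running_var")

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Tensor(np.ones(c, dtype=_DTYPE), requires_grad=True)
        self.bias = Tensor(np.zeros(c, dtype=_DTYPE), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=_DTYPE)
        self.running_var = np.ones(c, dtype=_DTYPE)

    def forward(self, x: Tensor) -> Tensor:
        gamma, beta = self.weight, self.bias
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x.data - mu[None, :, None, None]) / std[None, :, None, None]
        val = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
        out = Tensor(val, x.requires_grad or gamma.requires_grad, (x, gamma, beta))
        training = self.training

        def bwd(g):
            if gamma.requires_grad:
                gamma._accumulate(np.sum(g * xhat, axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accumulate(np.sum(g, axis=(0, 2, 3)))
            if x.requires_grad:
                gs = gamma.data[None, :, None, None] / std[None, :, None, None]
                if training:
                    mg = g.mean(axis=(0, 2, 3), keepdims=True)
                    mgx = (g * xhat).mean(axis=(0, 2, 3), keepdims=True)
                    x._accumulate(gs * (g - mg - xhat * mgx))
                else:
                    x._accumulate(gs * g)

        out._backward = bwd
        return out


class LayerNorm(Module):
    """Normalises the last axis (the channel axis of token rows)."""

    def __init__(self, c: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Tensor(np.ones(c, dtype=_DTYPE), requires_grad=True)
        self.bias = Tensor(np.zeros(c, dtype=_DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        gamma, beta = self.weight, self.bias
        mu = x.data.mean(axis=-1, keepdims=True)
        var = x.data.var(axis=-1, keepdims=True)
        std = np.sqrt(var + self.eps)
        xhat = (x.data - mu) / std
        val = gamma.data * xhat + beta.data
        out = Tensor(val, x.requires_grad or gamma.requires_grad, (x, gamma, beta))
        red = tuple(range(x.data.ndim - 1))

        def bwd(g):
            if gamma.requires_grad:
                gamma._accumulate(np.sum(g * xhat, axis=red))
            if beta.requires_grad:
                beta._accumulate(np.sum(g, axis=red))
            if x.requires_grad:
                gg = g * gamma.data
                mg = gg.mean(axis=-1, keepdims=True)
                mgx = (gg * xhat).mean(axis=-1, keepdims=True)
                x._accumulate((gg - mg - xhat * mgx) / std)

        out._backward = bwd
        return out


class Linear(Module):
    def __init__(self, cin: int, cout: int, bias: bool = True,
                 rng: np.random.Generator | None = None, zero_init: bool = False):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if zero_init:
            w = np.zeros((cin, cout), dtype=_DTYPE)
        else:
            bound = math.sqrt(6.0 / (cin + cout))  # Xavier-uniform
            w = rng.uniform(-bound, bound, (cin, cout)).astype(_DTYPE)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = (Tensor(np.zeros(cout, dtype=_DTYPE), requires_grad=True)
                     if bias else None)

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class ConvBnAct(Module):
    """Conv → BatchNorm → SiLU, the standard YOLO convolution unit."""

    def __init__(self, cin, cout, k=3, stride=1, rng=None):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return silu(self.bn(self.conv(x)))


# ----------------------------------------------------------------- optimiser

class AdamW:
    """AdamW with decoupled weight decay.

    Decay is applied only to parameters of rank ≥ 2 (conv / linear weights);
    biases and normalisation parameters are excluded, the usual convention.
    """

    def __init__(self, params: list[Tensor], lr: float = 0.01,
                 betas: tuple[float, float] = (0.937, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0005):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            update = (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)
            if p.data.ndim >= 2 and self.weight_decay:
                update = update + self.weight_decay * p.data
            p.data -= (self.lr * update).astype(p.data.dtype)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
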