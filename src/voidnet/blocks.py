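"""Detector building blocks: ResConv, tokenized attention, C2fCS fusion.

Two surfaces are exposed:

* **functional, numpy** — :func:`tokenize` / :func:`untokenize` /
  :func:`token_attention` / :func:`scaled_dot_attention` operate on plain
  ``H×W×C`` arrays and are the reference semantics of the tokenized
  attention mechanism;
* **trainable layers** — :class:`ResConv`, :class:`TokAtt`, :class:`C2f`,
  :class:`C2fCS` are autodiff modules in NCHW layout used by the detector.
  Thin wrappers (:func:`resconv_forward`, :func:`tokatt_forward`,
  :func:`c2fcs_forward`) run a layer on a single ``H×W×C`` array.

Tokenized attention partitions a feature map into an ``S×S`` grid of
non-overlapping spatial tokens and runs scaled dot-product self-attention
*within* each token independently, with parameters shared across tokens —
attention cost drops from ``(HW)²`` to ``S²·(HW/S²)²`` and, by
construction, no information crosses token boundaries before the final
output projection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, silu
from .nnlayers import (BatchNorm2d, Conv2d, ConvBnAct, DWConv2d, LayerNorm,
                       Linear, Module, ModuleList)

__all__ = [
    "TokenGrid",
    "tokenize",
    "untokenize",
    "scaled_dot_attention",
    "token_attention",
    "ResConv",
    "TokAtt",
    "C2f",
    "C2fCS",
    "resconv_forward",
    "tokatt_forward",
    "c2fcs_forward",
]


# ------------------------------------------------------------- tokenization

@dataclass
class TokenGrid:
    """An S×S grid of spatial tokens, each ``(H/S) × (W/S) × C``.

    ``tokens`` has shape ``(S, S, H/S, W/S, C)`` in row-major grid order;
    concatenating the tokens reconstructs the source feature map exactly.
    """

    tokens: np.ndarray
    S: int

    def __post_init__(self):
        if self.tokens.ndim != 5 or self.tokens.shape[0] != self.S \
                or self.tokens.shape[1] != self.S:
            raise ValueError(
                f"tokens must have shape (S, S, h, w, C) with S={self.S}, "
                f"got {self.tokens.shape}")


def tokenize(x: np.ndarray, S: int) -> TokenGrid:
    """Partition an H×W×C map into S² non-overlapping tokens."""
    x = np.asarray(x)
    if x.ndim != 3:
        raise ValueError(f"expected an H×W×C array, got shape {x.shape}")
    H, W, C = x.shape
    if S < 1:
        raise ValueError(f"S must be a positive integer, got {S}")
    if H % S or W % S:
        raise ValueError(f"S={S} does not evenly divide the feature map: H={H}, W={W}")
    h, w = H // S, W // S
    tokens = x.reshape(S, h, S, w, C).transpose(0, 2, 1, 3, 4)
    return TokenGrid(tokens=np.ascontiguousarray(tokens), S=S)


def untokenize(t: TokenGrid) -> np.ndarray:
    """Exact inverse of :func:`tokenize` (row-major grid placement)."""
    S, S2, h, w, C = t.tokens.shape
    return np.ascontiguousarray(
        t.tokens.transpose(0, 2, 1, 3, 4).reshape(S * h, S * w, C))


# ---------------------------------------------------------------- attention

def scaled_dot_attention(q: np.ndarray, k: np.ndarray, v: np.ndarray,
                         scale: float | None = None):
    """``softmax(QKᵀ/scale)·V`` in numpy; returns (output, weights).

    ``scale`` defaults to √C, C being the key/query channel width.  Each
    weight row is a softmax output: non-negative, summing to one.
    """
    q, k, v = (np.asarray(a, dtype=np.float64) for a in (q, k, v))
    c = q.shape[-1]
    scale = math.sqrt(c) if scale is None else float(scale)
    logits = q @ k.T / scale
    logits -= logits.max(axis=-1, keepdims=True)
    e = np.exp(logits)
    weights = e / e.sum(axis=-1, keepdims=True)
    return weights @ v, weights


def token_attention(t: TokenGrid, p: dict) -> TokenGrid:
    """Per-token self-attention with shared C×C projections.

    ``p`` maps ``"wq"``/``"wk"``/``"wv"`` to C×C matrices (row-vector
    convention, ``Q = X·Wq``) and optionally ``"bq"``/``"bk"``/``"bv"`` to
    biases.  Every token is processed independently; nothing crosses token
    boundaries.
    """
    S, _, h, w, C = t.tokens.shape
    for key in ("wq", "wk", "wv"):
        m = np.asarray(p[key])
        if m.shape != (C, C):
            raise ValueError(f"projection {key!r} must be {C}×{C}, got {m.shape}")
    wq, wk, wv = (np.asarray(p[k], dtype=np.float64) for k in ("wq", "wk", "wv"))
    bq = np.asarray(p.get("bq", np.zeros(C)), dtype=np.float64)
    bk = np.asarray(p.get("bk", np.zeros(C)), dtype=np.float64)
    bv = np.asarray(p.get("bv", np.zeros(C)), dtype=np.float64)
    out = np.empty_like(t.tokens, dtype=np.float64)
    for i in range(S):
        for j in range(S):
            rows = t.tokens[i, j].reshape(h * w, C)
            q, k, v = rows @ wq + bq, rows @ wk + bk, rows @ wv + bv
            att, _ = scaled_dot_attention(q, k, v)
            out[i, j] = att.reshape(h, w, C)
    return TokenGrid(tokens=out, S=S)


# ------------------------------------------------------------------- layers

class ResConv(Module):
    """Residual convolution: serial Conv→DWConv with an additive skip.

    ``y = Conv₃ₓ₃,stride(x); out = N(y + DWConv₃ₓ₃(y))`` where ``N`` is
    BatchNorm + SiLU (both optional).  The skip carries the standard
    convolution's output past the depthwise stage, so the wiring is at once
    serial (composition) and parallel (additive skip), and stays
    shape-compatible at any stride without projections.  The depthwise
    kernel is zero-initialised, making the block a plain convolution at
    initialisation.
    """

    def __init__(self, cin: int, cout: int, stride: int = 1,
                 norm: bool = True, act: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {stride}")
        self.cin, self.cout, self.stride = cin, cout, stride
        self.conv = Conv2d(cin, cout, 3, stride, bias=not norm, rng=rng)
        self.dw = DWConv2d(cout, 3, 1, bias=True, rng=rng)
        self.dw.weight.data[...] = 0.0
        self.norm = BatchNorm2d(cout) if norm else None
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cin:
            raise ValueError(
                f"ResConv expects {self.cin} input channels, got {x.shape[1]}")
        y = self.conv(x)
        z = y + self.dw(y)
        if self.norm is not None:
            z = self.norm(z)
        return silu(z) if self.act else z


class TokAtt(Module):
    """Tokenized single-head (optionally multi-head) self-attention block.

    Pipeline per the tokenized-attention mechanism: LayerNorm over channels
    → linear embedding (C→C) → split into S² spatial tokens → scaled
    dot-product attention within each token (scale √(C/heads)) → token
    fusion back to H×W×C → output linear map, with an outer residual skip
    ``x + block(x)``.  The output projection is zero-initialised so the
    block is the identity at initialisation.
    """

    def __init__(self, c: int, S: int, heads: int = 1, residual: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if S < 1:
            raise ValueError(f"S must be positive, got {S}")
        if c % heads:
            raise ValueError(f"heads={heads} must divide channels={c}")
        self.c, self.S, self.heads, self.residual = c, S, heads, residual
        self.ln = LayerNorm(c)
        self.embed = Linear(c, c, rng=rng)
        self.wq = Linear(c, c, rng=rng)
        self.wk = Linear(c, c, rng=rng)
        self.wv = Linear(c, c, rng=rng)
        self.proj = Linear(c, c, rng=rng, zero_init=True)

    def forward(self, x: Tensor, return_inner: bool = False):
        n, c, H, W = x.shape
        if c != self.c:
            raise ValueError(f"TokAtt expects {self.c} channels, got {c}")
        S = self.S
        if H % S or W % S:
            raise ValueError(f"S={S} does not evenly divide the feature map: H={H}, W={W}")
        h, w = H // S, W // S
        ch = c // self.heads
        # NCHW -> (N·S², hw, C) token rows
        rows = (x.transpose(0, 2, 3, 1)
                 .reshape(n, S, h, S, w, c)
                 .transpose(0, 1, 3, 2, 4, 5)
                 .reshape(n * S * S, h * w, c))
        t = self.embed(self.ln(rows))
        q, k, v = self.wq(t), self.wk(t), self.wv(t)
        if self.heads > 1:
            def split(z):
                return z.reshape(n * S * S, h * w, self.heads, ch).transpose(0, 2, 1, 3)
            q, k, v = split(q), split(k), split(v)
        logits = ad.matmul(q, k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2))
        att = ad.softmax(logits * (1.0 / math.sqrt(ch)), axis=-1)
        out = ad.matmul(att, v)
        if self.heads > 1:
            out = out.transpose(0, 2, 1, 3).reshape(n * S * S, h * w, c)
        # fuse tokens back to the spatial layout
        inner = (out.reshape(n, S, S, h, w, c)
                    .transpose(0, 1, 3, 2, 4, 5)
                    .reshape(n, H, W, c))
        y = self.proj(inner).transpose(0, 3, 1, 2)
        if self.residual:
            y = x + y
        if return_inner:
            return y, inner
        return y


class _CIB(Module):
    """Compact inverted bottleneck: DW3×3 → PW expand ×2 → PW reduce, with
    a residual skip."""

    def __init__(self, c: int, rng=None):
        super().__init__()
        self.dw = DWConv2d(c, 3, 1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(c)
        self.expand = ConvBnAct(c, 2 * c, k=1, rng=rng)
        self.reduce = Conv2d(2 * c, c, 1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(c)

    def forward(self, x: Tensor) -> Tensor:
        y = silu(self.bn1(self.dw(x)))
        y = self.bn2(self.reduce(self.expand(y)))
        return silu(x + y)


class C2f(Module):
    """CSP-style split–transform–concat fusion with compact inverted
    bottlenecks: a 1×1 conv splits into two halves, ``n`` bottlenecks chain
    on the second half, and all intermediate maps are concatenated and
    fused by a final 1×1 conv."""

    def __init__(self, cin: int, cout: int, n: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cin, self.cout = cin, cout
        h = max(cout // 2, 1)
        self.h = h
        self.cv1 = ConvBnAct(cin, 2 * h, k=1, rng=rng)
        self.blocks = ModuleList([_CIB(h, rng=rng) for _ in range(n)])
        self.cv2 = ConvBnAct((2 + n) * h, cout, k=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cin:
            raise ValueError(f"C2f expects {self.cin} input channels, got {x.shape[1]}")
        y = self.cv1(x)
        a, b = y[:, :self.h], y[:, self.h:]
        parts = [a, b]
        for blk in self.blocks:
            parts.append(blk(parts[-1]))
        return self.cv2(ad.concat(parts, axis=1))


class C2fCS(Module):
    """C2f fusion with a TokAtt block appended — attention-augmented feature
    fusion ahead of the small-object head."""

    def __init__(self, cin: int, cout: int, S: int, n: int = 1, heads: int = 1,
                 residual: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        self.c2f = C2f(cin, cout, n=n, rng=rng)
        self.att = TokAtt(cout, S, heads=heads, residual=residual, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.att(self.c2f(x))


# ------------------------------------------------- single-image HWC wrappers

def _hwc_to_tensor(x: np.ndarray) -> Tensor:
    x = np.asarray(x)
    if x.ndim != 3:
        raise ValueError(f"expected an H×W×C array, got shape {x.shape}")
    return Tensor(x.transpose(2, 0, 1)[None].astype(np.float32))


def _tensor_to_hwc(t: Tensor) -> np.ndarray:
    return np.ascontiguousarray(t.data[0].transpose(1, 2, 0))


def resconv_forward(x: np.ndarray, block: ResConv) -> np.ndarray:
    """Run a ResConv block on one H×W×C map (inference mode)."""
    was = block.training
    block.eval()
    try:
        return _tensor_to_hwc(block(_hwc_to_tensor(x)))
    finally:
        block.train(was)


def tokatt_forward(x: np.ndarray, block: TokAtt) -> np.ndarray:
    """Run a TokAtt block on one H×W×C map (inference mode)."""
    was = block.training
    block.eval()
    try:
        return _tensor_to_hwc(block(_hwc_to_tensor(x)))
    finally:
        block.train(was)


def c2fcs_forward(x: np.ndarray, block: C2fCS) -> np.ndarray:
    """Run a C2fCS block on one H×W×C map (inference mode)."""
    was = block.training
    block.eval()
    try:
        return _tensor_to_hwc(block(_hwc_to_tensor(x)))
    finally:
        block.train(was)
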