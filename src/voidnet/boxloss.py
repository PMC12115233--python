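"""Bounding-box overlap losses: IoU, CIoU, MPDIoU and the combined CMIoU.

All boxes are axis-aligned and given in continuous pixel corner coordinates
``(x1, y1, x2, y2)`` with the origin at the top-left and y growing downward.
Areas are ``(x2-x1)·(y2-y1)`` exactly; the half-open/closed distinction does
not arise for continuous coordinates.

The scalar API works in float64 and returns a :class:`LossBreakdown` so each
penalty term can be inspected and tested in isolation.  The batched
:func:`cmiou_loss_batch` builds the same quantities on autodiff tensors and
is what the training loop differentiates.

The CMIoU loss combines three penalties on top of ``1 − IoU``:

* the squared distance between the two top-left corners plus the squared
  distance between the two bottom-right corners, normalised by ``H² + W²``
  of the image frame (the MPDIoU corner penalty);
* the squared centre distance over the squared enclosing-box diagonal;
* the CIoU aspect-ratio consistency term ``α·v``.

Because the corner and centre penalties are positive for any displaced box,
the loss has a nonzero gradient even when the boxes do not overlap — the
regime where plain ``1 − IoU`` is flat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "ImageFrame",
    "LossBreakdown",
    "validate_box",
    "iou",
    "ciou_loss",
    "mpdiou_terms",
    "mpdiou",
    "cmiou_loss",
    "compose_total_loss",
    "cmiou_loss_batch",
    "cmiou_grad",
]

#: denominator floor for the aspect-ratio term of degenerate predictions
_H_CLAMP = 1e-7


@dataclass(frozen=True)
class ImageFrame:
    """Image height and width in pixels; normaliser of the corner penalty."""

    h: float
    w: float

    def __post_init__(self):
        if not (self.h > 0 and self.w > 0):
            raise ValueError(f"ImageFrame must be positive, got H={self.h}, W={self.w}")


@dataclass(frozen=True)
class LossBreakdown:
    """Per-term decomposition of a CIoU/CMIoU evaluation.

    ``total`` is always the exact sum of the reported penalties:
    ``1 - iou + mpd_penalty + rho2/c2 + alpha*v`` (CIoU sets
    ``mpd_penalty = 0``).
    """

    iou: float
    rho2: float
    c2: float
    v: float
    alpha: float
    d1sq: float
    d2sq: float
    mpd_penalty: float
    total: float


def validate_box(b, name: str = "box") -> np.ndarray:
    b = np.asarray(b, dtype=np.float64)
    if b.shape != (4,):
        raise ValueError(f"{name} must have 4 coordinates (x1, y1, x2, y2), got shape {b.shape}")
    x1, y1, x2, y2 = b
    if x2 < x1:
        raise ValueError(f"{name} is invalid: x2={x2} < x1={x1}")
    if y2 < y1:
        raise ValueError(f"{name} is invalid: y2={y2} < y1={y1}")
    return b


def _area(b: np.ndarray) -> float:
    return float((b[2] - b[0]) * (b[3] - b[1]))


def iou(a, b) -> float:
    """Intersection over union of two boxes; 0 for disjoint or doubly
    degenerate (both zero-area) pairs."""
    a = validate_box(a, "a")
    b = validate_box(b, "b")
    iw = min(a[2], b[2]) - max(a[0], b[0])
    ih = min(a[3], b[3]) - max(a[1], b[1])
    inter = max(iw, 0.0) * max(ih, 0.0)
    union = _area(a) + _area(b) - inter
    if union <= 0.0:
        return 0.0
    return float(inter / union)


def _aspect_v(pred: np.ndarray, gt: np.ndarray) -> float:
    wg, hg = gt[2] - gt[0], gt[3] - gt[1]
    wp, hp = pred[2] - pred[0], pred[3] - pred[1]
    # degenerate predictions: keep the ratio finite, preserving gradients
    rg = wg / max(hg, _H_CLAMP)
    rp = wp / max(hp, _H_CLAMP)
    return float((4.0 / math.pi ** 2) * (math.atan(rg) - math.atan(rp)) ** 2)


def _center_terms(pred: np.ndarray, gt: np.ndarray) -> tuple[float, float]:
    pcx, pcy = (pred[0] + pred[2]) / 2.0, (pred[1] + pred[3]) / 2.0
    gcx, gcy = (gt[0] + gt[2]) / 2.0, (gt[1] + gt[3]) / 2.0
    rho2 = (pcx - gcx) ** 2 + (pcy - gcy) ** 2
    ex1, ey1 = min(pred[0], gt[0]), min(pred[1], gt[1])
    ex2, ey2 = max(pred[2], gt[2]), max(pred[3], gt[3])
    c2 = (ex2 - ex1) ** 2 + (ey2 - ey1) ** 2
    return float(rho2), float(c2)


def ciou_loss(pred, gt) -> LossBreakdown:
    """Complete-IoU loss: ``1 - IoU + ρ²/c² + α·v``."""
    pred = validate_box(pred, "pred")
    gt = validate_box(gt, "gt")
    if _area(gt) <= 0.0:
        raise ValueError("gt box is degenerate (zero area)")
    i = iou(pred, gt)
    rho2, c2 = _center_terms(pred, gt)
    v = _aspect_v(pred, gt)
    denom = (1.0 - i) + v
    alpha = 0.0 if denom == 0.0 else v / denom
    total = 1.0 - i + (rho2 / c2 if c2 > 0 else 0.0) + alpha * v
    return LossBreakdown(iou=i, rho2=rho2, c2=c2, v=v, alpha=alpha,
                         d1sq=0.0, d2sq=0.0, mpd_penalty=0.0, total=total)


def mpdiou_terms(pred, gt) -> tuple[float, float]:
    """Squared distances between top-left corners and bottom-right corners."""
    pred = validate_box(pred, "pred")
    gt = validate_box(gt, "gt")
    d1sq = (pred[0] - gt[0]) ** 2 + (pred[1] - gt[1]) ** 2
    d2sq = (pred[2] - gt[2]) ** 2 + (pred[3] - gt[3]) ** 2
    return float(d1sq), float(d2sq)


def mpdiou(pred, gt, frame: ImageFrame) -> float:
    """Minimum-point-distance IoU similarity: ``IoU − (d1²+d2²)/(H²+W²)``.

    This is a similarity score (higher is better, can be negative), kept in
    the exact printed form; the trainable objective is :func:`cmiou_loss`.
    """
    if not isinstance(frame, ImageFrame):
        frame = ImageFrame(*frame)
    d1sq, d2sq = mpdiou_terms(pred, gt)
    return iou(pred, gt) - (d1sq + d2sq) / (frame.h ** 2 + frame.w ** 2)


def cmiou_loss(pred, gt, frame: ImageFrame) -> LossBreakdown:
    """Combined loss: ``1 − IoU + (d1²+d2²)/(H²+W²) + ρ²/c² + α·v``.

    Zero exactly when ``pred == gt``; positive otherwise, with a nonzero
    gradient even for disjoint boxes.
    """
    if not isinstance(frame, ImageFrame):
        frame = ImageFrame(*frame)
    pred = validate_box(pred, "pred")
    gt = validate_box(gt, "gt")
    if _area(gt) <= 0.0:
        raise ValueError("gt box is degenerate (zero area)")
    base = ciou_loss(pred, gt)
    d1sq, d2sq = mpdiou_terms(pred, gt)
    mpd_pen = (d1sq + d2sq) / (frame.h ** 2 + frame.w ** 2)
    return LossBreakdown(iou=base.iou, rho2=base.rho2, c2=base.c2, v=base.v,
                         alpha=base.alpha, d1sq=d1sq, d2sq=d2sq,
                         mpd_penalty=mpd_pen, total=base.total + mpd_pen)


def compose_total_loss(cls_term, box_term, obj_term, weights=(1.0, 1.0, 1.0)):
    """Weighted sum of the three detection loss components.

    Accepts plain numbers or autodiff tensors.  Weights must be
    non-negative; numeric terms must be finite and non-negative.
    """
    wc, wb, wo = (float(w) for w in weights)
    if min(wc, wb, wo) < 0:
        raise ValueError(f"loss weights must be non-negative, got {weights}")
    for name, t in (("cls", cls_term), ("box", box_term), ("obj", obj_term)):
        if not isinstance(t, Tensor):
            t = float(t)
            if not math.isfinite(t) or t < 0:
                raise ValueError(f"{name} term must be finite and >= 0, got {t}")
    return wc * cls_term + wb * box_term + wo * obj_term


# ------------------------------------------------------------ batched tensor

def cmiou_loss_batch(pred: Tensor, gt: np.ndarray, frame: ImageFrame,
                     kind: str = "cmiou") -> Tensor:
    """Differentiable per-pair loss for matched boxes.

    Parameters
    ----------
    pred : Tensor of shape (P, 4), corner coordinates, requires grad.
    gt : constant array of shape (P, 4).
    frame : the image frame normalising the corner penalty.
    kind : ``"cmiou"`` (default) or ``"ciou"``.

    Returns a Tensor of shape (P,).  α is treated as a stop-gradient weight,
    the CIoU-literature convention.
    """
    if kind not in ("cmiou", "ciou"):
        raise ValueError(f"unknown box loss kind: {kind!r}")
    if not isinstance(frame, ImageFrame):
        frame = ImageFrame(*frame)
    gt = np.asarray(gt, dtype=np.float64)
    px1, py1 = pred[:, 0], pred[:, 1]
    px2, py2 = pred[:, 2], pred[:, 3]
    gx1, gy1, gx2, gy2 = gt[:, 0], gt[:, 1], gt[:, 2], gt[:, 3]

    iw = ad.clip(ad.minimum(px2, gx2) - ad.maximum(px1, gx1), 0.0, None)
    ih = ad.clip(ad.minimum(py2, gy2) - ad.maximum(py1, gy1), 0.0, None)
    inter = iw * ih
    area_p = (px2 - px1) * (py2 - py1)
    area_g = (gx2 - gx1) * (gy2 - gy1)
    iou_t = inter / (area_p + area_g - inter + 1e-9)

    pcx, pcy = (px1 + px2) * 0.5, (py1 + py2) * 0.5
    gcx, gcy = (gx1 + gx2) * 0.5, (gy1 + gy2) * 0.5
    rho2 = (pcx - gcx) ** 2 + (pcy - gcy) ** 2
    ew = ad.maximum(px2, gx2) - ad.minimum(px1, gx1)
    eh = ad.maximum(py2, gy2) - ad.minimum(py1, gy1)
    c2 = ew ** 2 + eh ** 2 + 1e-9
    center_pen = rho2 / c2

    rp = (px2 - px1) / ad.maximum(py2 - py1, _H_CLAMP)
    rg = np.arctan((gx2 - gx1) / np.maximum(gy2 - gy1, _H_CLAMP))
    v = (4.0 / math.pi ** 2) * (Tensor(rg) - rp.arctan()) ** 2
    alpha = v.data / ((1.0 - iou_t.data) + v.data + 1e-9)  # stop-grad weight
    total = 1.0 - iou_t + center_pen + Tensor(alpha) * v
    if kind == "cmiou":
        d1sq = (px1 - gx1) ** 2 + (py1 - gy1) ** 2
        d2sq = (px2 - gx2) ** 2 + (py2 - gy2) ** 2
        total = total + (d1sq + d2sq) / (frame.h ** 2 + frame.w ** 2)
    return total


def cmiou_grad(pred, gt, frame: ImageFrame, kind: str = "cmiou") -> np.ndarray:
    """Analytic gradient of the scalar loss w.r.t. the predicted corners."""
    pred = validate_box(pred, "pred")
    p = Tensor(pred.reshape(1, 4), requires_grad=True)
    loss = cmiou_loss_batch(p, np.asarray(gt, dtype=np.float64).reshape(1, 4),
                            frame, kind=kind).sum()
    loss.backward()
    return p.grad.reshape(4).copy()
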