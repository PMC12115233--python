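"""A scaled-down anchor-free YOLO-style detector.

Topology: a ResConv backbone with five stride-2 stages (P3/P4/P5 taps at
strides 8/16/32), an FPN top-down + PAN bottom-up neck, and three one-to-many
detection heads.  A C2fCS block (CSP fusion + tokenized attention) sits
immediately before the stride-8 head, the highest-resolution head that
carries the small objects.

Head parameterisation is FCOS-style: each grid cell predicts four
non-negative distances (left, top, right, bottom) via softplus, scaled by
the stride, around the cell centre, plus an objectness logit and one logit
per class.  With all box logits at zero a cell decodes to a box centred on
``((c+0.5)s, (r+0.5)s)`` — the documented decode origin.

The reference configuration (``nano``) keeps the topology of the full-scale
model at roughly quarter width so that CPU training at reduced input sizes
is practical; the topology, not the capacity, is the contract.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .blocks import C2f, C2fCS, ResConv, TokAtt
from .boxloss import ImageFrame, cmiou_loss_batch, compose_total_loss, iou
from .nnlayers import Conv2d, ConvBnAct, Module, ModuleList, upsample2x

__all__ = [
    "DetectorConfig",
    "Detection",
    "Detector",
    "build_detector",
    "decode_predictions",
    "nms",
    "assign_targets",
    "detection_loss",
    "export_feature_maps",
    "save_checkpoint",
    "load_checkpoint",
]

STRIDES = (8, 16, 32)
#: GT-to-scale routing by box side sqrt(area): small -> stride 8, etc.
SCALE_SIZE_THRESHOLDS = (32.0, 96.0)
#: per-scale objectness balance (small objects dominate the stride-8 grid)
OBJ_BALANCE = {8: 4.0, 16: 1.0, 32: 0.4}


@dataclass
class DetectorConfig:
    """Architecture + inference configuration of the detector."""

    img_size: int = 640
    in_channels: int = 1
    num_classes: int = 1
    S: int = 4                 # tokens per side in the TokAtt block
    heads: int = 1
    channels: tuple = (16, 32, 64, 96, 128)   # stem, stage1..stage4
    width: float = 1.0
    use_resconv: bool = True
    use_tokatt: bool = True
    tokatt_residual: bool = True
    conf_thresh: float = 0.25
    nms_iou: float = 0.45
    class_names: tuple = ("void",)

    def __post_init__(self):
        if self.img_size % 32:
            raise ValueError(f"img_size={self.img_size} must be divisible by 32")
        if (self.img_size // 8) % self.S:
            raise ValueError(
                f"S={self.S} must divide the stride-8 grid "
                f"({self.img_size}//8 = {self.img_size // 8})")
        if len(self.channels) != 5:
            raise ValueError("channels must list 5 stage widths")

    def scaled_channels(self) -> tuple:
        return tuple(max(4, int(round(c * self.width))) for c in self.channels)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channels"] = list(self.channels)
        d["class_names"] = list(self.class_names)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorConfig":
        d = dict(d)
        d["channels"] = tuple(d.get("channels", (16, 32, 64, 96, 128)))
        d["class_names"] = tuple(d.get("class_names", ("void",)))
        return cls(**d)


def nano_config(img_size: int = 160, **kw) -> DetectorConfig:
    """The nano reference configuration used by the desk-scale demos:
    the full topology at roughly quarter width, sized for CPU training."""
    return DetectorConfig(img_size=img_size, channels=(8, 16, 32, 48, 64), **kw)


@dataclass
class Detection:
    """One decoded detection: pixel corner box, confidence, class."""

    box: np.ndarray          # (4,) x1 y1 x2 y2, pixels
    score: float
    class_id: int = 0


class Detector(Module):
    """Backbone + neck + three detection heads (see module docstring)."""

    def __init__(self, cfg: DetectorConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        c0, c1, c2, c3, c4 = cfg.scaled_channels()
        nc = cfg.num_classes

        def down(cin, cout):
            if cfg.use_resconv:
                return ResConv(cin, cout, stride=2, rng=rng)
            return ConvBnAct(cin, cout, 3, stride=2, rng=rng)

        # backbone
        self.stem = down(cfg.in_channels, c0)
        self.d1 = down(c0, c1)
        self.c1 = C2f(c1, c1, rng=rng)
        self.d2 = down(c1, c2)
        self.c2 = C2f(c2, c2, rng=rng)
        self.d3 = down(c2, c3)
        self.c3 = C2f(c3, c3, rng=rng)
        self.d4 = down(c3, c4)
        self.c4 = C2f(c4, c4, rng=rng)
        # neck: FPN top-down
        self.td4 = C2f(c3 + c4, c3, rng=rng)
        self.td3 = C2f(c2 + c3, c2, rng=rng)
        if cfg.use_tokatt:
            self.p3_fuse = C2fCS(c2, c2, S=cfg.S, heads=cfg.heads,
                                 residual=cfg.tokatt_residual, rng=rng)
        else:
            self.p3_fuse = C2f(c2, c2, rng=rng)
        # PAN bottom-up
        self.dn3 = ConvBnAct(c2, c2, 3, stride=2, rng=rng)
        self.bu4 = C2f(c2 + c3, c3, rng=rng)
        self.dn4 = ConvBnAct(c3, c3, 3, stride=2, rng=rng)
        self.bu5 = C2f(c3 + c4, c4, rng=rng)
        # heads: shared 3x3 conv then 1x1 to (4 box + 1 obj + nc cls)
        self.heads = ModuleList()
        for ci in (c2, c3, c4):
            stemc = ConvBnAct(ci, ci, 3, rng=rng)
            out = Conv2d(ci, 4 + 1 + nc, 1, bias=True, rng=rng)
            # bias the objectness logit toward a low prior for stable starts
            out.bias.data[4] = -4.0
            h = Module()
            h.stem = stemc
            h.out = out
            self.heads.append(h)

    # ------------------------------------------------------------- forward
    def forward(self, x: Tensor, collect_features: bool = False):
        cfg = self.cfg
        n, c, h, w = x.shape
        if c != cfg.in_channels or h != cfg.img_size or w != cfg.img_size:
            raise ValueError(
                f"expected input (N, {cfg.in_channels}, {cfg.img_size}, "
                f"{cfg.img_size}), got {tuple(x.shape)}")
        feats: dict[str, np.ndarray] = {}

        def tap(name, t):
            if collect_features:
                feats[name] = t.data.copy()

        y = self.stem(x); tap("backbone.stem", y)
        y = self.c1(self.d1(y)); tap("backbone.stage1", y)
        p3 = self.c2(self.d2(y)); tap("backbone.stage2", p3)
        p4 = self.c3(self.d3(p3)); tap("backbone.stage3", p4)
        p5 = self.c4(self.d4(p4)); tap("backbone.stage4", p5)

        n4 = self.td4(ad.concat([p4, upsample2x(p5)], axis=1))
        n3 = self.td3(ad.concat([p3, upsample2x(n4)], axis=1))
        o3 = self.p3_fuse(n3); tap("neck.p3", o3)
        n4b = self.bu4(ad.concat([n4, self.dn3(o3)], axis=1)); tap("neck.p4", n4b)
        n5 = self.bu5(ad.concat([p5, self.dn4(n4b)], axis=1)); tap("neck.p5", n5)

        raw = {}
        for name, feat, head in zip(("p3", "p4", "p5"), (o3, n4b, n5), self.heads):
            raw[name] = head.out(head.stem(feat))
        if collect_features:
            return raw, feats
        return raw

    def feature_stage_names(self) -> list[str]:
        return ["backbone.stem", "backbone.stage1", "backbone.stage2",
                "backbone.stage3", "backbone.stage4",
                "neck.p3", "neck.p4", "neck.p5"]


def build_detector(cfg: DetectorConfig, seed: int = 0) -> Detector:
    """Deterministically build a detector; equal seeds give bit-identical
    parameters."""
    return Detector(cfg, seed=seed)


# ------------------------------------------------------------------ decode

def _softplus_np(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid_np(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def decode_predictions(raw: dict, cfg: DetectorConfig,
                       conf_thresh: float | None = None,
                       max_det: int = 300) -> list[list[Detection]]:
    """Map raw head outputs to per-image lists of clipped detections.

    Cell (r, c) at stride s decodes to a box ``centre ± softplus(ltrb)·s``
    with centre ``((c+0.5)s, (r+0.5)s)``; score = σ(obj)·σ(cls).
    """
    conf = cfg.conf_thresh if conf_thresh is None else conf_thresh
    nc = cfg.num_classes
    batch = next(iter(raw.values()))
    n = batch.data.shape[0] if isinstance(batch, Tensor) else batch.shape[0]
    out: list[list[Detection]] = [[] for _ in range(n)]
    for name, stride in zip(("p3", "p4", "p5"), STRIDES):
        arr = raw[name].data if isinstance(raw[name], Tensor) else raw[name]
        _, ch, gh, gw = arr.shape
        if ch != 5 + nc:
            raise ValueError(f"head {name} has {ch} channels, expected {5 + nc}")
        ltrb = _softplus_np(arr[:, :4]) * stride
        obj = _sigmoid_np(arr[:, 4])
        cls = _sigmoid_np(arr[:, 5:])
        cxg, cyg = np.meshgrid((np.arange(gw) + 0.5) * stride,
                               (np.arange(gh) + 0.5) * stride)
        for i in range(n):
            score_map = obj[i][None] * cls[i]          # (nc, gh, gw)
            best_cls = score_map.argmax(axis=0)
            best_score = score_map.max(axis=0)
            rr, cc = np.nonzero(best_score >= conf)
            if len(rr) == 0:
                continue
            l, t, r_, b = (ltrb[i, j, rr, cc] for j in range(4))
            boxes = np.stack([cxg[rr, cc] - l, cyg[rr, cc] - t,
                              cxg[rr, cc] + r_, cyg[rr, cc] + b], axis=1)
            np.clip(boxes, 0, cfg.img_size, out=boxes)
            scores = best_score[rr, cc]
            classes = best_cls[rr, cc]
            out[i].extend(Detection(box=boxes[j], score=float(scores[j]),
                                    class_id=int(classes[j]))
                          for j in range(len(rr)))
    for i in range(n):
        out[i].sort(key=lambda d: -d.score)
        del out[i][max_det:]
    return out


def nms(dets: list[Detection], iou_thresh: float) -> list[Detection]:
    """Greedy class-aware non-maximum suppression, stable in score order."""
    if not (0 < iou_thresh <= 1):
        raise ValueError(f"iou_thresh must lie in (0, 1], got {iou_thresh}")
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    kept: list[Detection] = []
    for i in order:
        d = dets[i]
        ok = True
        for k in kept:
            if k.class_id == d.class_id and iou(k.box, d.box) >= iou_thresh:
                ok = False
                break
        if ok:
            kept.append(d)
    return kept


# -------------------------------------------------------------- assignment

def assign_targets(gt_per_image: list[np.ndarray], cfg: DetectorConfig):
    """One-to-many target assignment.

    ``gt_per_image[i]`` is an (G, 5) array of ``class, x1, y1, x2, y2`` in
    pixels.  Each GT is routed to one scale by √area thresholds and matched
    to its containing cell plus the two nearest neighbour cells (the
    sub-cell-offset rule).  Returns per-scale dicts with the objectness
    target map and the flat indices / boxes / classes of positive cells.
    """
    n = len(gt_per_image)
    out = {}
    for name, stride in zip(("p3", "p4", "p5"), STRIDES):
        g = cfg.img_size // stride
        obj = np.zeros((n, g, g), dtype=np.float32)
        taken: dict[tuple, int] = {}
        idx, boxes, classes = [], [], []
        out[name] = dict(stride=stride, grid=g, obj=obj, idx=idx,
                         boxes=boxes, classes=classes, taken=taken)
    for i, gts in enumerate(gt_per_image):
        for row in np.asarray(gts, dtype=np.float64).reshape(-1, 5):
            cls_id, x1, y1, x2, y2 = row
            side = np.sqrt(max(x2 - x1, 0.0) * max(y2 - y1, 0.0))
            if side <= SCALE_SIZE_THRESHOLDS[0]:
                name = "p3"
            elif side <= SCALE_SIZE_THRESHOLDS[1]:
                name = "p4"
            else:
                name = "p5"
            sc = out[name]
            s, g = sc["stride"], sc["grid"]
            cx, cy = (x1 + x2) / 2 / s, (y1 + y2) / 2 / s
            c0, r0 = int(np.clip(np.floor(cx), 0, g - 1)), int(np.clip(np.floor(cy), 0, g - 1))
            cells = [(r0, c0)]
            fx, fy = cx - np.floor(cx), cy - np.floor(cy)
            c_nb = c0 - 1 if fx < 0.5 else c0 + 1
            r_nb = r0 - 1 if fy < 0.5 else r0 + 1
            if 0 <= c_nb < g:
                cells.append((r0, c_nb))
            if 0 <= r_nb < g:
                cells.append((r_nb, c0))
            for r, c in cells:
                key = (i, r, c)
                if key in sc["taken"]:
                    continue               # first GT wins a contested cell
                sc["taken"][key] = 1
                sc["obj"][i, r, c] = 1.0
                sc["idx"].append(i * g * g + r * g + c)
                sc["boxes"].append([x1, y1, x2, y2])
                sc["classes"].append(int(cls_id))
    for sc in out.values():
        sc["idx"] = np.asarray(sc["idx"], dtype=np.int64)
        sc["boxes"] = np.asarray(sc["boxes"], dtype=np.float64).reshape(-1, 4)
        sc["classes"] = np.asarray(sc["classes"], dtype=np.int64)
        del sc["taken"]
    return out


def _bce_logits(z: Tensor, y: np.ndarray) -> Tensor:
    """Elementwise binary cross-entropy on logits: softplus(z) − z·y."""
    return ad.softplus(z) - z * Tensor(np.asarray(y, dtype=z.dtype))


def detection_loss(raw: dict, targets: dict, cfg: DetectorConfig,
                   loss_kind: str = "cmiou",
                   weights: tuple = (0.5, 5.0, 1.0)):
    """Composite detection loss.

    Box term: CMIoU (or CIoU) averaged over assigned cells; classification
    and objectness: binary cross-entropy on logits, objectness balanced
    per scale.  Returns ``(total, components)`` with components as floats.
    """
    nc = cfg.num_classes
    frame = ImageFrame(cfg.img_size, cfg.img_size)
    obj_terms, cls_terms, box_sums = [], [], []
    n_pos = 0
    for name, stride in zip(("p3", "p4", "p5"), STRIDES):
        t = targets[name]
        arr = raw[name]
        n, ch, g, _ = arr.shape
        obj_logit = arr[:, 4]
        obj_terms.append(_bce_logits(obj_logit, t["obj"]).mean() * OBJ_BALANCE[stride])
        if len(t["idx"]) == 0:
            continue
        rows = arr.reshape(n, ch, g * g).transpose(0, 2, 1).reshape(n * g * g, ch)
        pos = rows[t["idx"]]
        # box: decode positive cells to corner coordinates
        cells = t["idx"] % (g * g)
        ccx = ((cells % g) + 0.5) * stride
        ccy = ((cells // g) + 0.5) * stride
        ltrb = ad.softplus(pos[:, :4]) * float(stride)
        px1 = Tensor(ccx) - ltrb[:, 0]
        py1 = Tensor(ccy) - ltrb[:, 1]
        px2 = Tensor(ccx) + ltrb[:, 2]
        py2 = Tensor(ccy) + ltrb[:, 3]
        pred_boxes = ad.stack([px1, py1, px2, py2], axis=1)
        box_sums.append(cmiou_loss_batch(pred_boxes, t["boxes"], frame,
                                         kind=loss_kind).sum())
        n_pos += len(t["idx"])
        cls_target = np.zeros((len(t["idx"]), nc), dtype=np.float32)
        cls_target[np.arange(len(t["idx"])), t["classes"]] = 1.0
        cls_terms.append(_bce_logits(pos[:, 5:], cls_target).mean())
    obj_term = obj_terms[0]
    for t in obj_terms[1:]:
        obj_term = obj_term + t
    if n_pos:
        box_term = box_sums[0]
        for t in box_sums[1:]:
            box_term = box_term + t
        box_term = box_term * (1.0 / n_pos)
        cls_term = cls_terms[0]
        for t in cls_terms[1:]:
            cls_term = cls_term + t
        cls_term = cls_term * (1.0 / len(cls_terms))
    else:
        box_term = Tensor(0.0)
        cls_term = Tensor(0.0)
    total = compose_total_loss(cls_term, box_term, obj_term, weights)
    comps = {"box": float(box_term.data), "cls": float(cls_term.data),
             "obj": float(obj_term.data), "total": float(total.data)}
    return total, comps


# ---------------------------------------------------------------- artefacts

def export_feature_maps(model: Detector, image: np.ndarray,
                        stage_names: list[str], out_dir) -> dict[str, np.ndarray]:
    """Dump named stage activations: raw ``.npy`` plus a channel-mean
    heat-map PNG whose dimensions equal the stage's H×W.  Deterministic for
    a fixed model and input."""
    from PIL import Image

    valid = model.feature_stage_names()
    for s in stage_names:
        if s not in valid:
            raise ValueError(f"unknown stage {s!r}; valid stages: {valid}")
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 2:
        img = img[None]
    else:
        img = img.transpose(2, 0, 1)
    was = model.training
    model.eval()
    try:
        _, feats = model(Tensor(img[None]), collect_features=True)
    finally:
        model.train(was)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    exported = {}
    for s in stage_names:
        a = feats[s][0]                      # (C, H, W)
        np.save(out_dir / (s.replace(".", "_") + ".npy"), a)
        heat = a.mean(axis=0)
        lo, hi = heat.min(), heat.max()
        norm = (heat - lo) / (hi - lo) if hi > lo else np.zeros_like(heat)
        Image.fromarray((norm * 255).astype(np.uint8), mode="L").save(
            out_dir / (s.replace(".", "_") + ".png"))
        exported[s] = a
    return exported


def save_checkpoint(model: Detector, path) -> None:
    """Parameters + buffers (npz) with config and seed embedded as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = json.dumps({"config": model.cfg.to_dict(), "seed": model.seed})
    with open(path, "wb") as f:
        np.savez(f, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **model.state_dict())


def load_checkpoint(path) -> Detector:
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    cfg = DetectorConfig.from_dict(meta["config"])
    model = Detector(cfg, seed=meta["seed"])
    model.load_state_dict(state)
    return model
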