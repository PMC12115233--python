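"""Training loop, evaluation driver and run logging.

The optimizer defaults follow the YOLO-family training convention: AdamW at learning
rate 0.01, batch size 16, first-moment coefficient 0.937 (the "momentum"
parameter mapped to beta1, with beta2 = 0.999) and weight decay 0.0005.
Schedules are off by default (a cosine decay is available behind a flag),
early stopping is disabled, and every random choice — shuffling, mosaic
composition, parameter init — derives from the run seed, so a run is
bit-reproducible on one machine.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .evaluation import EvalReport, map_over_thresholds
from .model import (Detection, Detector, DetectorConfig, assign_targets,
                    build_detector, decode_predictions, detection_loss,
                    load_checkpoint, nms, save_checkpoint)
from .nnlayers import AdamW
from .autodiff import Tensor
from .synthetic import LabeledImage, letterbox_resize, load_manifest, \
    load_split, mosaic_augment

__all__ = ["TrainConfig", "RunLog", "train", "evaluate", "predict_images",
           "demo_train_config", "overfit_train_config"]


@dataclass
class TrainConfig:
    """Optimisation settings (defaults per the YOLO-family convention)."""

    optimizer: str = "adamw"
    lr: float = 0.01
    batch_size: int = 16
    beta1: float = 0.937
    weight_decay: float = 0.0005
    epochs: int = 50
    mosaic: bool = True
    mosaic_prob: float = 0.5
    loss: str = "cmiou"            # "cmiou" | "ciou"
    loss_weights: tuple = (0.5, 5.0, 1.0)
    lr_schedule: str = "constant"  # "constant" | "cosine"
    seed: int = 0
    eval_conf_thresh: float = 0.05

    def __post_init__(self):
        if self.lr < 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("need lr >= 0, batch_size >= 1, epochs >= 1")
        if self.loss not in ("cmiou", "ciou"):
            raise ValueError(f"loss must be 'cmiou' or 'ciou', got {self.loss!r}")
        if self.optimizer.lower() != "adamw":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class RunLog:
    """One record per completed epoch plus the config snapshots."""

    train_config: dict
    model_config: dict
    epochs: list = field(default_factory=list)
    wall_time_s: float = 0.0

    def append(self, **rec):
        self.epochs.append(rec)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def demo_train_config(seed: int = 0, epochs: int = 50) -> TrainConfig:
    """Desk-scale demo settings: the default optimizer at cosine decay,
    mosaic off (on tiny easy sets it mostly destroys the few positives)."""
    return TrainConfig(lr=0.01, batch_size=16, epochs=epochs, mosaic=False,
                       lr_schedule="cosine", seed=seed)


def overfit_train_config(seed: int = 0, epochs: int = 200) -> TrainConfig:
    """Single-image overfit settings used by the sanity check."""
    return TrainConfig(lr=0.005, batch_size=1, epochs=epochs, mosaic=False,
                       seed=seed)


def _prep_items(items, img_size: int) -> list[LabeledImage]:
    out = []
    for it in items:
        if it.image.shape[0] != img_size or it.image.shape[1] != img_size:
            it = letterbox_resize(it, img_size)
        out.append(it)
    return out


def _to_batch(items: list[LabeledImage], img_size: int):
    imgs = np.stack([it.image for it in items]).astype(np.float32)
    x = Tensor(imgs[:, None] * 2.0 - 1.0)     # map [0,1] -> [-1,1]
    gts = []
    for it in items:
        rows = [[a.class_id, *a.to_xyxy(img_size)] for a in it.annotations]
        gts.append(np.asarray(rows, dtype=np.float64).reshape(-1, 5))
    return x, gts


def _resolve_splits(data):
    """Accept a manifest path/dict or a (train_items, val_items) pair."""
    if isinstance(data, (str, Path)):
        data = load_manifest(data)
    if isinstance(data, dict):
        return load_split(data, "train"), load_split(data, "val")
    train_items, val_items = data
    return list(train_items), list(val_items)


def train(model_cfg: DetectorConfig, data, t: TrainConfig,
          out_dir=None) -> tuple[Detector, RunLog]:
    """Train a detector; returns the final model and the run log.

    ``data`` is a dataset manifest (path or dict) or a pair of item lists.
    When ``out_dir`` is given, ``best.npz`` (highest val mAP50), ``last.npz``
    and ``runlog.json`` are written there.
    """
    t0 = time.time()
    train_items, val_items = _resolve_splits(data)
    if not train_items:
        raise ValueError("empty training set")
    train_items = _prep_items(train_items, model_cfg.img_size)
    val_items = _prep_items(val_items, model_cfg.img_size)

    model = build_detector(model_cfg, seed=t.seed)
    opt = AdamW(model.parameters(), lr=t.lr, betas=(t.beta1, 0.999),
                weight_decay=t.weight_decay)
    rng = np.random.default_rng(t.seed)
    log = RunLog(train_config=asdict(t), model_config=model_cfg.to_dict())
    best_map = -1.0
    n = len(train_items)
    steps_per_epoch = max(1, n // t.batch_size)

    for epoch in range(t.epochs):
        if t.lr_schedule == "cosine":
            opt.lr = t.lr * 0.5 * (1.0 + np.cos(np.pi * epoch / max(t.epochs - 1, 1)))
        model.train()
        order = rng.permutation(n)
        comps_sum = {"box": 0.0, "cls": 0.0, "obj": 0.0, "total": 0.0}
        for step in range(steps_per_epoch):
            idx = order[step * t.batch_size:(step + 1) * t.batch_size]
            if len(idx) == 0:
                continue
            batch_items = []
            for i in idx:
                it = train_items[i]
                if t.mosaic and rng.random() < t.mosaic_prob:
                    partners = rng.integers(0, n, size=3)
                    it = mosaic_augment(
                        [it] + [train_items[j] for j in partners],
                        out_size=model_cfg.img_size,
                        seed=int(rng.integers(0, 2 ** 31)))
                batch_items.append(it)
            x, gts = _to_batch(batch_items, model_cfg.img_size)
            raw = model(x)
            targets = assign_targets(gts, model_cfg)
            loss, comps = detection_loss(raw, targets, model_cfg,
                                         loss_kind=t.loss,
                                         weights=t.loss_weights)
            if not np.isfinite(comps["total"]):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch} step {step}; images: "
                    f"{[train_items[i].identifier for i in idx]}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            for k in comps_sum:
                comps_sum[k] += comps[k]
        rec = {"epoch": epoch,
               **{f"train_{k}": v / steps_per_epoch for k, v in comps_sum.items()},
               "lr": opt.lr}
        if val_items:
            report = _evaluate_items(model, val_items, model_cfg,
                                     conf_thresh=t.eval_conf_thresh)
            rec.update(val_map50=report.map50, val_map50_95=report.map50_95,
                       val_recall=report.recall, val_precision=report.precision)
            if out_dir is not None and report.map50 > best_map:
                best_map = report.map50
                save_checkpoint(model, Path(out_dir) / "best.npz")
        log.append(**rec)
    log.wall_time_s = time.time() - t0
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(model, out_dir / "last.npz")
        log.save(out_dir / "runlog.json")
    return model, log


def predict_images(model: Detector, items: list[LabeledImage],
                   conf_thresh: float | None = None,
                   nms_iou: float | None = None) -> list[list[Detection]]:
    """Decode + NMS for a list of labelled (or unlabelled) images."""
    cfg = model.cfg
    model.eval()
    dets: list[list[Detection]] = []
    bs = 16
    for lo in range(0, len(items), bs):
        x, _ = _to_batch(items[lo:lo + bs], cfg.img_size)
        raw = model(x)
        decoded = decode_predictions(raw, cfg, conf_thresh=conf_thresh)
        for dd in decoded:
            dets.append(nms(dd, nms_iou if nms_iou is not None else cfg.nms_iou))
    return dets


def _evaluate_items(model: Detector, items: list[LabeledImage],
                    cfg: DetectorConfig, conf_thresh: float = 0.05) -> EvalReport:
    dets = predict_images(model, items, conf_thresh=conf_thresh)
    gts = []
    for it in items:
        rows = [[a.class_id, *a.to_xyxy(cfg.img_size)] for a in it.annotations]
        gts.append(np.asarray(rows, dtype=np.float64).reshape(-1, 5))
    return map_over_thresholds(dets, gts)


def evaluate(model_or_checkpoint, data, conf_thresh: float = 0.05,
             split: str = "val") -> EvalReport:
    """Deterministic evaluation of a model or checkpoint on a dataset split."""
    if isinstance(model_or_checkpoint, (str, Path)):
        model = load_checkpoint(model_or_checkpoint)
    else:
        model = model_or_checkpoint
    cfg = model.cfg
    if isinstance(data, (str, Path)):
        data = load_manifest(data)
    if isinstance(data, dict):
        names = data.get("names", {})
        if len(names) != cfg.num_classes:
            raise ValueError(
                f"dataset has {len(names)} classes, model expects {cfg.num_classes}")
        items = load_split(data, split)
    else:
        items = list(data)
    if not items:
        raise ValueError(f"empty {split} set: cannot produce a valid report")
    items = _prep_items(items, cfg.img_size)
    return _evaluate_items(model, items, cfg, conf_thresh=conf_thresh)
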