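"""From-scratch detection metrics: greedy matching, precision/recall,
101-point interpolated average precision, mAP50 and mAP50-95.

Matching follows the YOLO-family convention: predictions are processed in
descending score order; each prediction matches the not-yet-matched ground
truth of the same class and image with the highest IoU, provided that IoU
reaches the threshold (a true positive); otherwise it is a false positive.
Unmatched ground truths are false negatives.  Ties in score are broken by
insertion order, deterministically.

AP uses the COCO-style 101-point interpolation: the precision envelope is
made non-increasing in recall, sampled at recall 0.00, 0.01, …, 1.00, and
averaged.  mAP50-95 averages AP over IoU thresholds 0.50:0.05:0.95 and then
over classes.

The reported scalar recall/precision pair is taken at the confidence
threshold maximising F1 on the evaluation set (at IoU 0.5).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .boxloss import iou

__all__ = [
    "MatchResult",
    "PRCurve",
    "EvalReport",
    "match_detections",
    "precision_recall",
    "average_precision",
    "map_over_thresholds",
    "read_detections_file",
    "write_detections_file",
]

IOU_THRESHOLDS_50_95 = tuple(np.round(np.arange(0.5, 0.96, 0.05), 2))


@dataclass
class MatchResult:
    """Per-prediction TP/FP flags in descending-score order."""

    tp: np.ndarray            # bool, score-descending order
    scores: np.ndarray        # float, same order
    n_gt: int

    def __post_init__(self):
        self.tp = np.asarray(self.tp, dtype=bool)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.tp.sum() > self.n_gt:
            raise ValueError("more true positives than ground truths")


@dataclass
class PRCurve:
    """Cumulative (recall, precision) points after each prediction."""

    recall: np.ndarray
    precision: np.ndarray

    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.recall.tolist(), self.precision.tolist()))


@dataclass
class EvalReport:
    """Headline detection metrics."""

    map50: float
    map50_95: float
    precision: float          # at the F1-maximising confidence threshold
    recall: float
    f1_threshold: float
    ap_per_class: dict = field(default_factory=dict)   # {class: {iou_t: AP}}
    n_gt: int = 0
    valid: bool = True

    def to_json(self, path) -> None:
        d = dict(self.__dict__)
        d["ap_per_class"] = {str(k): {str(t): float(a) for t, a in v.items()}
                             for k, v in self.ap_per_class.items()}
        Path(path).write_text(json.dumps(d, indent=2))


def _as_det_arrays(dets_img):
    """Normalise one image's detections to (classes, scores, boxes)."""
    if len(dets_img) == 0:
        return (np.zeros(0, dtype=int), np.zeros(0), np.zeros((0, 4)))
    cls, sc, bx = [], [], []
    for d in dets_img:
        if hasattr(d, "box"):
            cls.append(d.class_id); sc.append(d.score); bx.append(d.box)
        else:
            c, s, *b = d
            cls.append(int(c)); sc.append(float(s)); bx.append(b)
    return np.asarray(cls, int), np.asarray(sc, float), np.asarray(bx, float).reshape(-1, 4)


def _as_gt_arrays(gts_img):
    if len(gts_img) == 0:
        return np.zeros(0, dtype=int), np.zeros((0, 4))
    arr = np.asarray(gts_img, dtype=float).reshape(-1, 5)
    return arr[:, 0].astype(int), arr[:, 1:]


def match_detections(dets, gts, iou_thresh: float,
                     class_id: int | None = None) -> MatchResult:
    """Greedy score-ordered matching across a list of images.

    ``dets[i]``: detections of image i (``Detection`` objects or
    ``(class, score, x1, y1, x2, y2)`` rows); ``gts[i]``: ground truths as
    ``(class, x1, y1, x2, y2)`` rows.  ``class_id`` restricts both sides to
    one class.
    """
    if not (0 < iou_thresh < 1):
        raise ValueError(f"iou_thresh must lie in (0, 1), got {iou_thresh}")
    if len(dets) != len(gts):
        raise ValueError("dets and gts must cover the same images")
    records = []   # (score, insertion order, image, class, box)
    order = 0
    for i, dd in enumerate(dets):
        cls, sc, bx = _as_det_arrays(dd)
        for c, s, b in zip(cls, sc, bx):
            if class_id is None or c == class_id:
                records.append((float(s), order, i, int(c), b))
            order += 1
    records.sort(key=lambda r: (-r[0], r[1]))
    gt_cls, gt_box, gt_used = [], [], []
    n_gt = 0
    for gg in gts:
        c, b = _as_gt_arrays(gg)
        if class_id is not None:
            keep = c == class_id
            c, b = c[keep], b[keep]
        gt_cls.append(c); gt_box.append(b); gt_used.append(np.zeros(len(c), bool))
        n_gt += len(c)
    tp = np.zeros(len(records), dtype=bool)
    for j, (s, _, i, c, b) in enumerate(records):
        best, best_k = 0.0, -1
        for k in range(len(gt_cls[i])):
            if gt_used[i][k] or gt_cls[i][k] != c:
                continue
            ov = iou(b, gt_box[i][k])
            if ov > best:
                best, best_k = ov, k
        if best_k >= 0 and best >= iou_thresh:
            tp[j] = True
            gt_used[i][best_k] = True
    return MatchResult(tp=tp, scores=np.array([r[0] for r in records]), n_gt=n_gt)


def precision_recall(m: MatchResult) -> PRCurve:
    """Cumulative precision/recall after each prediction in score order."""
    if len(m.tp) == 0:
        return PRCurve(recall=np.zeros(0), precision=np.zeros(0))
    cum_tp = np.cumsum(m.tp)
    cum_fp = np.cumsum(~m.tp)
    precision = cum_tp / (cum_tp + cum_fp)
    if m.n_gt == 0:
        warnings.warn("no ground truths: recall reported as 0", stacklevel=2)
        recall = np.zeros_like(precision)
    else:
        recall = cum_tp / m.n_gt
    return PRCurve(recall=recall, precision=precision)


def average_precision(c: PRCurve) -> float:
    """101-point interpolated area under the PR curve."""
    if len(c.recall) == 0:
        return 0.0
    r = np.concatenate([[0.0], c.recall, [1.0]])
    p = np.concatenate([[0.0], c.precision, [0.0]])
    # non-increasing precision envelope
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    samples = np.linspace(0.0, 1.0, 101)
    idx = np.searchsorted(r, samples, side="left")
    return float(p[idx].mean())


def map_over_thresholds(dets, gts,
                        iou_thresholds=IOU_THRESHOLDS_50_95) -> EvalReport:
    """Evaluate mAP50 / mAP50-95 plus an F1-optimal precision/recall pair."""
    classes = sorted({int(c) for gg in gts for c in _as_gt_arrays(gg)[0]})
    n_gt = sum(len(_as_gt_arrays(gg)[0]) for gg in gts)
    if n_gt == 0:
        return EvalReport(map50=0.0, map50_95=0.0, precision=0.0, recall=0.0,
                          f1_threshold=0.0, n_gt=0, valid=False)
    ap: dict[int, dict[float, float]] = {c: {} for c in classes}
    for c in classes:
        for t in iou_thresholds:
            m = match_detections(dets, gts, float(t), class_id=c)
            ap[c][float(t)] = average_precision(precision_recall(m))
    t50 = next((float(t) for t in iou_thresholds if abs(float(t) - 0.5) < 1e-9),
               float(iou_thresholds[0]))
    map50 = float(np.mean([ap[c][t50] for c in classes]))
    map50_95 = float(np.mean([np.mean(list(ap[c].values())) for c in classes]))
    # operating point: maximise F1 over the 0.5-IoU match run (all classes)
    m = match_detections(dets, gts, 0.5)
    prec, rec, thr = 0.0, 0.0, 0.0
    if len(m.tp):
        cum_tp = np.cumsum(m.tp)
        cum_fp = np.cumsum(~m.tp)
        p = cum_tp / (cum_tp + cum_fp)
        r = cum_tp / m.n_gt
        f1 = 2 * p * r / np.maximum(p + r, 1e-12)
        j = int(np.argmax(f1))
        prec, rec, thr = float(p[j]), float(r[j]), float(m.scores[j])
    return EvalReport(map50=map50, map50_95=map50_95, precision=prec,
                      recall=rec, f1_threshold=thr, ap_per_class=ap,
                      n_gt=n_gt, valid=True)


# ---------------------------------------------------------------- text I/O

def write_detections_file(dets, path) -> None:
    """One line per detection: ``image_id class score x1 y1 x2 y2``."""
    lines = []
    for i, dd in enumerate(dets):
        cls, sc, bx = _as_det_arrays(dd)
        for c, s, b in zip(cls, sc, bx):
            lines.append(f"{i} {c} {s:.6f} " + " ".join(f"{v:.2f}" for v in b))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_detections_file(path, n_images: int) -> list[list[tuple]]:
    """Inverse of :func:`write_detections_file`."""
    out: list[list[tuple]] = [[] for _ in range(n_images)]
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"malformed detection line {ln}: {line!r}")
        i = int(parts[0])
        out[i].append((int(parts[1]), float(parts[2]), *map(float, parts[3:])))
    return out
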