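"""Detection metrics against an independent brute-force reference."""

import numpy as np
import pytest

from voidnet.evaluation import (MatchResult, PRCurve, average_precision,
                                map_over_thresholds, match_detections,
                                precision_recall, read_detections_file,
                                write_detections_file)
from conftest import random_box


# ------------------------------------------------------- brute-force oracle

def oracle_eval(dets, gts, iou_thresholds):
    """Single-file re-implementation: greedy matching, raw PR points,
    envelope AP by fine-grid numerical integration."""

    def box_iou(a, b):
        iw = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
        ih = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
        inter = iw * ih
        u = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
        return inter / u if u > 0 else 0.0

    classes = sorted({int(g[0]) for gg in gts for g in gg})
    ap = {}
    for cid in classes:
        ap[cid] = {}
        for t in iou_thresholds:
            recs = []
            order = 0
            for i, dd in enumerate(dets):
                for d in dd:
                    c, s, *b = d
                    if int(c) == cid:
                        recs.append((float(s), order, i, list(map(float, b))))
                    order += 1
            recs.sort(key=lambda r: (-r[0], r[1]))
            used = [set() for _ in gts]
            n_gt = sum(1 for gg in gts for g in gg if int(g[0]) == cid)
            tp = []
            for s, _, i, b in recs:
                cand = [(box_iou(b, list(map(float, g[1:]))), k)
                        for k, g in enumerate(gts[i])
                        if int(gts[i][k][0]) == cid and k not in used[i]]
                best = max(cand, default=(0.0, -1))
                if best[1] >= 0 and best[0] >= t:
                    tp.append(True)
                    used[i].add(best[1])
                else:
                    tp.append(False)
            # PR curve and envelope AP on a dense recall grid
            if not recs or n_gt == 0:
                ap[cid][t] = 0.0
                continue
            cum_tp = np.cumsum(tp)
            cum_fp = np.cumsum([not f for f in tp])
            prec = cum_tp / (cum_tp + cum_fp)
            rec = cum_tp / n_gt
            grid = np.linspace(0, 1, 101)
            interp = np.zeros_like(grid)
            for j, r0 in enumerate(grid):
                mask = rec >= r0 - 1e-12
                interp[j] = prec[mask].max() if mask.any() else 0.0
            ap[cid][t] = float(interp.mean())
    map50 = float(np.mean([ap[c][iou_thresholds[0]] for c in classes]))
    map5095 = float(np.mean([np.mean(list(ap[c].values())) for c in classes]))
    return ap, map50, map5095


def random_scenario(rng, n_images=3, n_classes=2):
    gts, dets = [], []
    for _ in range(n_images):
        gg = [[rng.integers(0, n_classes), *random_box(rng, 0, 100, 3)]
              for _ in range(rng.integers(0, 5))]
        dd = []
        for g in gg:
            if rng.random() < 0.7:          # jittered copy of a GT
                b = np.array(g[1:]) + rng.normal(0, 4, 4)
                b = [min(b[0], b[2] - 0.5), min(b[1], b[3] - 0.5),
                     max(b[0] + 0.5, b[2]), max(b[1] + 0.5, b[3])]
                dd.append((int(g[0]), float(rng.random()), *b))
        for _ in range(rng.integers(0, 4)):  # background false positives
            dd.append((int(rng.integers(0, n_classes)), float(rng.random()),
                       *random_box(rng, 0, 100, 2)))
        gts.append(gg)
        dets.append(dd)
    return dets, gts


# ----------------------------------------------------------------- matching

def test_match_simple_cases():
    gts = [[(0, 10, 10, 30, 30)]]
    dets = [[(0, 0.9, 12, 10, 30, 30)]]        # IoU 0.9 >= 0.5
    m = match_detections(dets, gts, 0.5)
    assert m.tp.tolist() == [True] and m.n_gt == 1
    dets = [[(0, 0.9, 10, 10, 30, 30), (0, 0.8, 10, 10, 30, 30)]]
    m = match_detections(dets, gts, 0.5)
    assert m.tp.tolist() == [True, False]      # single-match rule
    with pytest.raises(ValueError):
        match_detections(dets, gts, 1.5)


def test_match_against_oracle_random(rng):
    for _ in range(30):
        dets, gts = random_scenario(rng)
        for t in (0.3, 0.5, 0.75):
            m = match_detections(dets, gts, t)
            ap_o, _, _ = oracle_eval(dets, gts, [t])
            # same TP totals per class imply identical greedy assignment
            got_tp = int(m.tp.sum())
            want_tp = 0
            for cid in ap_o:
                mm = match_detections(dets, gts, t, class_id=cid)
                want_tp += int(mm.tp.sum())
            assert got_tp == want_tp
            assert m.tp.sum() <= m.n_gt


def test_tp_plus_fn_equals_gt(rng):
    for _ in range(20):
        dets, gts = random_scenario(rng)
        m = match_detections(dets, gts, 0.5)
        fn = m.n_gt - int(m.tp.sum())
        assert fn >= 0 and int(m.tp.sum()) + fn == m.n_gt


# --------------------------------------------------------------------- PR

def test_precision_recall_worked_example():
    m = MatchResult(tp=[True, False, True], scores=[0.9, 0.8, 0.7], n_gt=2)
    c = precision_recall(m)
    assert c.points() == [(0.5, 1.0), (0.5, 0.5), (1.0, 2 / 3)]
    m1 = MatchResult(tp=[True], scores=[1.0], n_gt=1)
    assert precision_recall(m1).points() == [(1.0, 1.0)]
    empty = precision_recall(MatchResult(tp=[], scores=[], n_gt=3))
    assert len(empty.recall) == 0


def test_precision_recall_no_gt_warns():
    m = MatchResult(tp=[False, False], scores=[0.9, 0.8], n_gt=0)
    with pytest.warns(UserWarning, match="no ground truths"):
        c = precision_recall(m)
    assert (c.recall == 0).all()
    np.testing.assert_allclose(c.precision, [0.0, 0.0])


# --------------------------------------------------------------------- AP

def test_ap_examples():
    assert average_precision(PRCurve(np.array([1.0]), np.array([1.0]))) == 1.0
    c = precision_recall(MatchResult(tp=[True, False, True],
                                     scores=[0.9, 0.8, 0.7], n_gt=2))
    ap = average_precision(c)
    # dense-envelope integral: 0.5*1.0 + 0.5*(2/3) = 0.8333…
    assert ap == pytest.approx(0.5 * 1.0 + 0.5 * (2 / 3), abs=0.01)
    assert average_precision(PRCurve(np.zeros(0), np.zeros(0))) == 0.0


def test_ap_invariant_to_trailing_fps_at_full_recall():
    base = MatchResult(tp=[True, True], scores=[0.9, 0.8], n_gt=2)
    more = MatchResult(tp=[True, True, False], scores=[0.9, 0.8, 0.1], n_gt=2)
    assert average_precision(precision_recall(base)) == \
        average_precision(precision_recall(more))


def _greedy_unmatched_gt(dets, gts, t=0.5):
    """Replicate the greedy rule to find one (image, gt_index) left unmatched."""
    from voidnet.boxloss import iou as biou
    recs = []
    order = 0
    for i, dd in enumerate(dets):
        for c, s, *b in dd:
            recs.append((float(s), order, i, int(c), b))
            order += 1
    recs.sort(key=lambda r: (-r[0], r[1]))
    used = [set() for _ in gts]
    for s, _, i, c, b in recs:
        cand = [(biou(b, g[1:]), k) for k, g in enumerate(gts[i])
                if int(g[0]) == c and k not in used[i]]
        best = max(cand, default=(0.0, -1))
        if best[1] >= 0 and best[0] >= t:
            used[i].add(best[1])
    for i, gg in enumerate(gts):
        for k in range(len(gg)):
            if k not in used[i]:
                return i, k
    return None


def test_ap_monotone_under_added_correct_detection(rng):
    for _ in range(20):
        dets, gts = random_scenario(rng)
        r0 = map_over_thresholds(dets, gts, iou_thresholds=(0.5,))
        if not r0.valid:
            continue
        # add a perfect, top-scored detection for a GT the greedy left unmatched
        hit = _greedy_unmatched_gt(dets, gts)
        if hit is None:
            continue
        i, k = hit
        g = gts[i][k]
        dets[i] = [(int(g[0]), 1.0, *g[1:])] + list(dets[i])
        r1 = map_over_thresholds(dets, gts, iou_thresholds=(0.5,))
        assert r1.map50 >= r0.map50 - 1e-12


# -------------------------------------------------------------------- mAP

def test_map_perfect_detections():
    gts = [[(0, 10, 10, 30, 30), (0, 50, 50, 60, 70)]]
    dets = [[(0, 1.0, 10, 10, 30, 30), (0, 1.0, 50, 50, 60, 70)]]
    r = map_over_thresholds(dets, gts)
    assert r.map50 == 1.0 and r.map50_95 == 1.0
    assert r.precision == 1.0 and r.recall == 1.0


def test_threshold_semantics():
    gts = [[(0, 0, 0, 10, 10)]]
    dets = [[(0, 0.9, 0, 0, 10, 6)]]           # IoU = 0.6
    r = map_over_thresholds(dets, gts, iou_thresholds=(0.5, 0.65))
    assert r.ap_per_class[0][0.5] == 1.0
    assert r.ap_per_class[0][0.65] == 0.0


def test_map_against_oracle_random_scenarios(rng):
    thresholds = tuple(np.round(np.arange(0.5, 0.96, 0.05), 2))
    for _ in range(100):
        dets, gts = random_scenario(rng)
        if sum(len(g) for g in gts) == 0:
            continue
        r = map_over_thresholds(dets, gts)
        ap_o, map50_o, map5095_o = oracle_eval(dets, gts, list(thresholds))
        assert r.map50 == pytest.approx(map50_o, abs=1e-9)
        assert r.map50_95 == pytest.approx(map5095_o, abs=1e-9)


def test_map5095_equals_mean_of_individual_aps(rng):
    dets, gts = random_scenario(rng)
    if sum(len(g) for g in gts) == 0:
        gts[0].append((0, 1, 1, 9, 9))
    r = map_over_thresholds(dets, gts)
    per_t = []
    for t in np.round(np.arange(0.5, 0.96, 0.05), 2):
        rt = map_over_thresholds(dets, gts, iou_thresholds=(float(t),))
        per_t.append(rt.map50)  # here "map50" is the AP at that threshold
    assert r.map50_95 == pytest.approx(np.mean(per_t), abs=1e-12)


def test_no_gt_flags_invalid():
    r = map_over_thresholds([[(0, 0.5, 0, 0, 5, 5)]], [[]])
    assert not r.valid


def test_detection_file_roundtrip(tmp_path, rng):
    dets, _ = random_scenario(rng)
    path = tmp_path / "dets.txt"
    write_detections_file(dets, path)
    back = read_detections_file(path, len(dets))
    for dd, bb in zip(dets, back):
        assert len(dd) == len(bb)
        for d, b in zip(dd, bb):
            assert d[0] == b[0]
            assert d[1] == pytest.approx(b[1], abs=1e-6)
            np.testing.assert_allclose(d[2:], b[2:], atol=0.01)
    (tmp_path / "bad.txt").write_text("0 0.5 1 2 3\n")
    with pytest.raises(ValueError, match="line 1"):
        read_detections_file(tmp_path / "bad.txt", 1)
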