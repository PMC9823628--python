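"""Decoding, NMS, matching, and metric arithmetic against independent
brute-force oracles."""

import dataclasses
import itertools

import numpy as np
import pytest

from pearnet.data_io import BoundingBox
from pearnet.evaluation import (AP_THRESHOLDS, EvalCounts, ap50_95,
                                average_precision, decode_and_nms, evaluate,
                                match_detections, nms, precision_recall_f1,
                                stratified_eval)
from pearnet.losses import iou


def box(cx, cy, w, h, conf=None, tags=None):
    return BoundingBox(0, cx, cy, w, h, confidence=conf, tags=tags)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def oracle_max_matching_tp(preds, gts, thr):
    """Maximum-cardinality assignment of predictions to ground truths with
    IoU >= thr, by exhaustive search (viable for <= 6 boxes)."""
    best = 0
    g_idx = range(len(gts))
    for k in range(min(len(preds), len(gts)), 0, -1):
        for p_sub in itertools.combinations(range(len(preds)), k):
            for g_perm in itertools.permutations(g_idx, k):
                if all(iou(preds[p], gts[g]) >= thr
                       for p, g in zip(p_sub, g_perm)):
                    return k
    return best


def oracle_ap(preds_imgs, gts_imgs, thr, grid=100001):
    """AP by fine-grid numeric integration of the interpolated PR curve,
    built from scratch (greedy confidence-ordered matching per image)."""
    rows = []
    for i, ps in enumerate(preds_imgs):
        for p in ps:
            rows.append((p.confidence, i, p))
    rows.sort(key=lambda r: -r[0])
    n_gt = sum(len(g) for g in gts_imgs)
    used = [set() for _ in gts_imgs]
    tps = []
    for conf, i, p in rows:
        ious = [(iou(p, g), j) for j, g in enumerate(gts_imgs[i])
                if j not in used[i]]
        ious.sort(key=lambda t: -t[0])
        if ious and ious[0][0] >= thr:
            used[i].add(ious[0][1])
            tps.append(1)
        else:
            tps.append(0)
    tp_c = np.cumsum(tps)
    fp_c = np.cumsum([1 - t for t in tps])
    rec = tp_c / n_gt
    prec = tp_c / (tp_c + fp_c)
    rs = np.linspace(0, 1, grid)
    ps = np.zeros(grid)
    for r, p in zip(rec, prec):  # interpolated precision: max over >= r
        ps[rs <= r] = np.maximum(ps[rs <= r], p)
    return float(np.trapezoid(ps, rs))


# ---------------------------------------------------------------------------
# NMS
# ---------------------------------------------------------------------------


def test_nms_single_box_identity():
    b = box(0.5, 0.5, 0.2, 0.2, conf=0.9)
    assert nms([b]) == [b]


def test_nms_suppresses_high_overlap_pair():
    a = box(0.2, 0.2, 0.4, 0.4, conf=0.9)
    # shifted down 0.1: IoU = 0.12/0.20 = 0.6
    b = box(0.2, 0.3, 0.4, 0.4, conf=0.8)
    assert iou(a, b) == pytest.approx(0.6)
    kept = nms([a, b], iou_threshold=0.5)
    assert kept == [a]
    assert set(map(id, nms([a, b], iou_threshold=0.7))) == {id(a), id(b)}


def test_nms_agrees_with_exhaustive_rule(rng):
    """Greedy NMS output equals direct application of the rule: keep a box
    iff no higher-confidence *kept* box overlaps it beyond the threshold."""
    for _ in range(30):
        boxes = [box(*rng.uniform(0.2, 0.8, 2), *rng.uniform(0.05, 0.4, 2),
                     conf=float(rng.random())) for _ in range(6)]
        kept = nms(boxes, 0.45)
        expected = []
        for b in sorted(boxes, key=lambda b: -b.confidence):
            if all(iou(b, k) <= 0.45 for k in expected):
                expected.append(b)
        assert kept == expected


def test_decode_and_nms_threshold_filters_everything(tiny_cfg, tiny_model):
    from pearnet.nn import Tensor
    tiny_model.eval()
    raw = tiny_model(Tensor(np.zeros((1, 3, 64, 64), dtype=np.float32)))
    # freshly initialised head biases put objectness well below 0.25
    out = decode_and_nms(raw, tiny_cfg, conf_threshold=0.25)
    assert out == [[]]
    with pytest.raises(ValueError):
        decode_and_nms(raw, tiny_cfg, conf_threshold=1.5)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


def test_match_perfect_and_empty():
    gts = [box(0.3, 0.3, 0.2, 0.2), box(0.7, 0.7, 0.2, 0.2)]
    preds = [dataclasses.replace(g, confidence=0.9) for g in gts]
    c = match_detections(preds, gts)
    assert (c.tp, c.fp, c.fn) == (2, 0, 0)
    c = match_detections([], gts)
    assert (c.tp, c.fp, c.fn) == (0, 0, 2)


def test_match_agrees_with_exhaustive_assignment_oracle(rng):
    """On scenes of well-separated objects (each prediction overlaps at
    most one ground truth), greedy matching attains the exhaustive
    maximum-assignment TP count."""
    for trial in range(25):
        centers = [(0.15 + 0.35 * i, 0.15 + 0.35 * j)
                   for i in range(3) for j in range(3)]
        rng.shuffle(centers)
        n_gt = int(rng.integers(1, 5))
        gts = [box(cx, cy, 0.12, 0.12) for cx, cy in centers[:n_gt]]
        preds = []
        for g in gts[:int(rng.integers(0, n_gt + 1))]:
            preds.append(box(g.cx + rng.uniform(-0.04, 0.04),
                             g.cy + rng.uniform(-0.04, 0.04),
                             0.12, 0.12, conf=float(rng.random())))
        preds += [box(*rng.uniform(0.3, 0.7, 2), 0.05, 0.05,
                      conf=float(rng.random()))
                  for _ in range(int(rng.integers(0, 3)))]
        c = match_detections(preds, gts, 0.5)
        assert c.tp == oracle_max_matching_tp(preds, gts, 0.5)
        assert c.tp + c.fn == len(gts)
        assert c.tp + c.fp == len(preds)


def test_precision_recall_f1_arithmetic():
    p, r, f1 = precision_recall_f1(EvalCounts(tp=8, fp=2, fn=4))
    assert p == pytest.approx(0.8)
    assert r == pytest.approx(2 / 3)
    assert f1 == pytest.approx(2 * 0.8 * (2 / 3) / (0.8 + 2 / 3))
    assert precision_recall_f1(EvalCounts(0, 0, 0)) == (0.0, 0.0, 0.0)
    p, r, f1 = precision_recall_f1(EvalCounts(3, 1, 1))
    assert min(p, r) <= f1 <= max(p, r)


# ---------------------------------------------------------------------------
# Average precision
# ---------------------------------------------------------------------------


def _toy_set(rng, n_img=3, max_gt=3):
    preds, gts = [], []
    for i in range(n_img):
        n_gt = int(rng.integers(1, max_gt + 1))
        g = [box(*rng.uniform(0.2, 0.8, 2), *rng.uniform(0.1, 0.3, 2))
             for _ in range(n_gt)]
        p = []
        for gt_box in g:
            if rng.random() < 0.8:
                p.append(box(gt_box.cx + rng.uniform(-0.08, 0.08),
                             gt_box.cy + rng.uniform(-0.08, 0.08),
                             gt_box.w, gt_box.h, conf=float(rng.random())))
        p += [box(*rng.uniform(0.2, 0.8, 2), 0.1, 0.1,
                  conf=float(rng.random()))
              for _ in range(int(rng.integers(0, 3)))]
        preds.append(p)
        gts.append(g)
    return preds, gts


def test_ap_perfect_and_all_wrong():
    gts = [[box(0.5, 0.5, 0.2, 0.2)]]
    perfect = [[box(0.5, 0.5, 0.2, 0.2, conf=0.9)]]
    wrong = [[box(0.1, 0.1, 0.05, 0.05, conf=0.9)]]
    assert average_precision(perfect, gts, 0.5) == pytest.approx(1.0)
    assert average_precision(wrong, gts, 0.5) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        average_precision(perfect, [[]], 0.5)


def test_ap_matches_brute_force_integration(rng):
    for _ in range(10):
        preds, gts = _toy_set(rng)
        got = average_precision(preds, gts, 0.5)
        want = oracle_ap(preds, gts, 0.5)
        assert got == pytest.approx(want, abs=2e-4)


def test_ap_invariant_to_monotone_confidence_rescale(rng):
    preds, gts = _toy_set(rng)
    base = average_precision(preds, gts, 0.5)
    squashed = [[dataclasses.replace(p, confidence=p.confidence ** 3 * 0.5)
                 for p in ps] for ps in preds]
    assert average_precision(squashed, gts, 0.5) == pytest.approx(base)


def test_ap_nonincreasing_in_iou_threshold_and_ap5095_mean(rng):
    preds, gts = _toy_set(rng, n_img=4)
    aps = [average_precision(preds, gts, t) for t in AP_THRESHOLDS]
    assert all(a >= b - 1e-12 for a, b in zip(aps, aps[1:]))
    assert ap50_95(preds, gts) == pytest.approx(np.mean(aps))
    assert aps[-1] <= aps[0]


def test_ap_11point_interpolation_close_to_allpoint(rng):
    preds, gts = _toy_set(rng)
    a = average_precision(preds, gts, 0.5, interpolation="all")
    b = average_precision(preds, gts, 0.5, interpolation="11point")
    assert abs(a - b) < 0.15  # same curve, coarser quadrature


# ---------------------------------------------------------------------------
# Stratified evaluation
# ---------------------------------------------------------------------------


def test_single_stratum_equals_overall(rng):
    preds, gts = _toy_set(rng)
    tagged = [[dataclasses.replace(g, tags={"illumination": "weak"})
               for g in gl] for gl in gts]
    tp_preds = [[dataclasses.replace(p, tags={"illumination": "weak"})
                 for p in ps] for ps in preds]
    overall = evaluate(tp_preds, tagged)
    strat = stratified_eval(tp_preds, tagged, "illumination", 640)
    assert set(strat) == {"weak"}
    assert strat["weak"] == overall


def test_disjoint_strata_tp_additivity():
    size = 640
    small = box(0.25, 0.25, 16 / size, 16 / size)        # radius 8 px
    large = box(0.75, 0.75, 120 / size, 120 / size)      # radius 60 px
    gts = [[small, large]]
    preds = [[dataclasses.replace(small, confidence=0.9),
              dataclasses.replace(large, confidence=0.9)]]
    strat = stratified_eval(preds, gts, "size", size)
    assert set(strat) == {"small", "large"}
    overall = evaluate(preds, gts)
    n_tp = sum(round(r.recall * r.n_gt) for r in strat.values())
    assert n_tp == round(overall.recall * overall.n_gt) == 2


def test_perfect_and_empty_detectors_per_stratum():
    size = 640
    gts = [[box(0.3, 0.3, 0.1, 0.1, tags={"viewpoint": "side"})],
           [box(0.6, 0.6, 0.1, 0.1, tags={"viewpoint": "birdseye"})]]
    preds = [[dataclasses.replace(gts[0][0], confidence=0.95)], []]
    strat = stratified_eval(preds, gts, "viewpoint", size)
    assert strat["side"].ap50 == pytest.approx(1.0)
    assert strat["side"].f1 == pytest.approx(1.0)
    assert strat["birdseye"].ap50 == pytest.approx(0.0)
    assert strat["birdseye"].f1 == 0.0


def test_omitted_size_boxes_excluded():
    size = 640
    tiny = box(0.5, 0.5, 6 / size, 6 / size)  # radius 3 px -> omitted
    ok = box(0.2, 0.2, 30 / size, 30 / size)
    strat = stratified_eval([[ ]], [[tiny, ok]], "size", size)
    assert "omitted" not in strat
    assert sum(r.n_gt for r in strat.values()) == 1
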