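"""IoU / EIoU arithmetic, invariances, and the composite detection loss."""

import dataclasses

import numpy as np
import pytest

from pearnet.arch import ModelConfig, build_model
from pearnet.data_io import BoundingBox
from pearnet.losses import DetectionLoss, eiou_loss, iou
from pearnet.nn import Tensor


def corner_box(x1, y1, x2, y2, size=10.0):
    return BoundingBox.from_xyxy(0, x1, y1, x2, y2, size=size)


# ---------------------------------------------------------------------------
# IoU
# ---------------------------------------------------------------------------


def test_iou_identical_disjoint_and_hand_case():
    a = corner_box(0, 0, 2, 2)
    b = corner_box(1, 1, 3, 3)
    c = corner_box(5, 5, 6, 6)
    assert iou(a, a) == pytest.approx(1.0)
    assert iou(a, c) == 0.0
    assert iou(a, b) == pytest.approx(1 / 7)  # areas 4+4, intersection 1


def test_iou_symmetric_and_bounded(rng):
    for _ in range(50):
        x1, y1, x2, y2 = np.sort(rng.random(4))
        u1, v1, u2, v2 = np.sort(rng.random(4))
        a = BoundingBox.from_xyxy(0, x1, y1, x2, y2)
        b = BoundingBox.from_xyxy(0, u1, v1, u2, v2)
        assert iou(a, b) == pytest.approx(iou(b, a))
        assert 0.0 <= iou(a, b) <= 1.0


def test_iou_degenerate_pair_is_zero():
    z = BoundingBox(0, 0.5, 0.5, 0.0, 0.0)
    assert iou(z, z) == 0.0


# ---------------------------------------------------------------------------
# EIoU
# ---------------------------------------------------------------------------


def test_eiou_zero_iff_identical(rng):
    a = corner_box(0, 0, 2, 2)
    assert eiou_loss(a, a) == 0.0
    b = corner_box(0.1, 0, 2.1, 2)
    assert eiou_loss(b, a) > 0.0


def test_eiou_hand_derived_pair():
    # centers distance^2 = 2, enclosure diag^2 = 18, equal widths/heights
    pred, gt = corner_box(0, 0, 2, 2), corner_box(1, 1, 3, 3)
    assert eiou_loss(pred, gt) == pytest.approx(6 / 7 + 2 / 18, rel=1e-6)


def test_eiou_at_least_one_minus_iou(rng):
    for _ in range(100):
        a = BoundingBox(0, *rng.uniform(0.3, 0.7, 2), *rng.uniform(0.05, 0.3, 2))
        b = BoundingBox(0, *rng.uniform(0.3, 0.7, 2), *rng.uniform(0.05, 0.3, 2))
        assert eiou_loss(a, b) >= 1.0 - iou(a, b) - 1e-12


def test_eiou_invariant_to_joint_translation_and_scale(rng):
    for _ in range(25):
        a = BoundingBox(0, *rng.uniform(0.3, 0.5, 2), *rng.uniform(0.05, 0.2, 2))
        b = BoundingBox(0, *rng.uniform(0.3, 0.5, 2), *rng.uniform(0.05, 0.2, 2))
        base = eiou_loss(a, b)
        dx, dy = rng.uniform(-0.1, 0.1, 2)
        s = rng.uniform(0.5, 2.0)
        shift = lambda t: dataclasses.replace(t, cx=t.cx + dx, cy=t.cy + dy)  # noqa: E731
        scale = lambda t: dataclasses.replace(t, cx=t.cx * s, cy=t.cy * s,  # noqa: E731
                                              w=t.w * s, h=t.h * s)
        assert eiou_loss(shift(a), shift(b)) == pytest.approx(base, rel=1e-6)
        assert eiou_loss(scale(a), scale(b)) == pytest.approx(base, rel=1e-5)


def test_eiou_decreases_as_center_approaches(rng):
    gt = BoundingBox(0, 0.6, 0.6, 0.2, 0.2)
    losses = []
    for t in np.linspace(0.0, 1.0, 11):
        pred = BoundingBox(0, 0.2 + 0.4 * t, 0.2 + 0.4 * t, 0.2, 0.2)
        losses.append(eiou_loss(pred, gt))
    assert all(l1 > l2 for l1, l2 in zip(losses, losses[1:]))


# ---------------------------------------------------------------------------
# Composite detection loss
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def small_head():
    cfg = ModelConfig(variant="baseline", input_size=64, width_multiple=0.25)
    model = build_model(cfg, seed=0)
    x = Tensor(np.random.default_rng(5).random((2, 3, 64, 64),
                                               dtype=np.float32))
    model.train()
    raw = model(x)
    return cfg, raw


def test_detection_loss_components_sum(small_head):
    cfg, raw = small_head
    loss_fn = DetectionLoss(cfg)
    targets = [[BoundingBox(0, 0.4, 0.5, 0.3, 0.35)], []]
    total, comps = loss_fn(raw, targets)
    nb = raw[0].shape[0]
    expected = (loss_fn.w_box * comps["box"] + loss_fn.w_obj * comps["obj"]
                + loss_fn.w_cls * comps["cls"]) * nb
    assert comps["total"] == pytest.approx(expected, rel=1e-5)
    assert comps["n_assigned"] > 0


def test_detection_loss_empty_images_trains_objectness_only(small_head):
    cfg, raw = small_head
    total, comps = DetectionLoss(cfg)(raw, [[], []])
    assert comps["box"] == 0.0 and comps["cls"] == 0.0
    assert comps["obj"] > 0.0


def test_detection_loss_objectness_vanishes_on_confident_background(small_head):
    cfg, raw = small_head
    quiet = [Tensor(np.concatenate(
        [np.zeros_like(r.data[..., :4]),
         np.full_like(r.data[..., 4:5], -20.0),
         np.zeros_like(r.data[..., 5:])], axis=-1)) for r in raw]
    _, comps = DetectionLoss(cfg)(quiet, [[], []])
    assert comps["obj"] < 1e-6


def test_detection_loss_matches_hand_assembly(small_head):
    """One-target toy: recompute the three components independently from
    the raw arrays and the published assignment rule."""
    cfg, raw = small_head
    loss_fn = DetectionLoss(cfg)
    target = BoundingBox(0, 0.52, 0.47, 0.25, 0.3)
    total, comps = loss_fn(raw, [[target], []])

    grids = [t.shape[2:4] for t in raw]
    assigned = loss_fn.build_targets([[target], []], grids)
    sig = lambda v: 1 / (1 + np.exp(-v))  # noqa: E731
    box_means, obj_sum, cls_means = [], 0.0, []
    for si, (p, (b, a, gj, gi, gt, anc)) in enumerate(zip(raw, assigned)):
        arr = p.data
        obj_t = np.zeros(arr.shape[:-1])
        if len(b):
            rows, cls_rows = [], []
            for k in range(len(b)):
                sel = arr[b[k], a[k], gj[k], gi[k]]
                cx = sig(sel[0]) * 2 - 0.5 + gi[k]
                cy = sig(sel[1]) * 2 - 0.5 + gj[k]
                w = (sig(sel[2]) * 2) ** 2 * anc[k][0]
                h = (sig(sel[3]) * 2) ** 2 * anc[k][1]
                pb = BoundingBox(0, cx, cy, w, h)
                gb = BoundingBox(0, *gt[k])
                rows.append(eiou_loss(pb, gb))
                obj_t[b[k], a[k], gj[k], gi[k]] = max(
                    obj_t[b[k], a[k], gj[k], gi[k]],
                    np.clip(iou(pb, gb), 0, 1))
                logit = sel[5]
                cls_rows.append(np.maximum(logit, 0) - logit * 1
                                + np.log1p(np.exp(-abs(logit))))
            box_means.append(np.mean(rows))
            cls_means.append(np.mean(cls_rows))
        x = arr[..., 4]
        bce = np.maximum(x, 0) - x * obj_t + np.log1p(np.exp(-np.abs(x)))
        obj_sum += bce.mean() * (4.0, 1.0, 0.4)[si]
    assert comps["box"] == pytest.approx(np.mean(box_means), rel=1e-4)
    assert comps["obj"] == pytest.approx(obj_sum, rel=1e-4)
    assert comps["cls"] == pytest.approx(np.mean(cls_means), rel=1e-4)
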