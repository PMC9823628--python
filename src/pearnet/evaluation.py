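"""Detection post-processing and the evaluation protocol.

Raw head outputs are decoded to normalised boxes (sigmoid offsets, anchor
priors), thresholded on confidence, and filtered by greedy class-agnostic
NMS.  Metrics follow the standard detection definitions: precision,
recall, F1 at a fixed confidence/IoU operating point (defaults 0.25/0.5),
and average precision as the area under the all-point-interpolated
precision-recall curve, at IoU 0.50 (AP50) and averaged over IoU
0.50:0.05:0.95 (AP50:95).  Results can be stratified by pear size class,
illumination regime, or viewpoint.
"""

from __future__ import annotations

import csv
import dataclasses
import io
import json

import numpy as np

from .data_io import BoundingBox, size_class
from .losses import iou_matrix

__all__ = [
    "EvalCounts", "EvalResult", "decode_raw", "nms", "decode_and_nms",
    "match_detections", "precision_recall_f1", "average_precision",
    "ap50_95", "evaluate", "stratified_eval", "result_table",
]

AP_THRESHOLDS = np.arange(0.50, 0.96, 0.05).round(2)


@dataclasses.dataclass
class EvalCounts:
    tp: int
    fp: int
    fn: int


@dataclasses.dataclass
class EvalResult:
    precision: float
    recall: float
    f1: float
    ap50: float | None
    ap50_95: float | None
    n_gt: int
    n_pred: int


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


# ---------------------------------------------------------------------------
# Decoding + NMS
# ---------------------------------------------------------------------------


def decode_raw(raw, cfg) -> list[list[BoundingBox]]:
    """Decode raw per-scale head tensors to normalised candidate boxes.

    ``raw`` is the head output: per scale, an array/Tensor of shape
    (batch, anchors, gh, gw, 5 + nc).  Confidence is
    sigmoid(objectness) * sigmoid(best class score).
    """
    anchors_px = cfg.scaled_anchors()
    batches: list[list[BoundingBox]] | None = None
    for si, p in enumerate(raw):
        a = p.data if hasattr(p, "data") else np.asarray(p)
        n, na, gh, gw, _ = a.shape
        if batches is None:
            batches = [[] for _ in range(n)]
        stride = cfg.input_size / gw
        s = _sigmoid(a)
        gi, gj = np.meshgrid(np.arange(gw), np.arange(gh))
        cx = (s[..., 0] * 2.0 - 0.5 + gi) * stride / cfg.input_size
        cy = (s[..., 1] * 2.0 - 0.5 + gj) * stride / cfg.input_size
        anc = anchors_px[si].reshape(1, na, 1, 1, 2)
        w = (s[..., 2] * 2.0) ** 2 * anc[..., 0] / cfg.input_size
        h = (s[..., 3] * 2.0) ** 2 * anc[..., 1] / cfg.input_size
        cls_conf = s[..., 5:].max(axis=-1)
        cls_id = s[..., 5:].argmax(axis=-1)
        conf = s[..., 4] * cls_conf
        for bi in range(n):
            sel = np.nonzero(conf[bi] > 1e-4)
            for ai, jj, ii in zip(*sel):
                batches[bi].append(BoundingBox(
                    int(cls_id[bi, ai, jj, ii]),
                    float(cx[bi, ai, jj, ii]), float(cy[bi, ai, jj, ii]),
                    float(w[bi, ai, jj, ii]), float(h[bi, ai, jj, ii]),
                    confidence=float(conf[bi, ai, jj, ii])).clipped())
    return batches or []


def nms(boxes: list[BoundingBox], iou_threshold: float = 0.5
        ) -> list[BoundingBox]:
    """Greedy class-agnostic non-maximum suppression by descending
    confidence."""
    if not boxes:
        return []
    order = sorted(boxes, key=lambda b: -(b.confidence or 0.0))
    xyxy = np.array([b.to_xyxy() for b in order])
    keep: list[int] = []
    for i in range(len(order)):
        ok = True
        if keep:
            ious = iou_matrix(xyxy[i], xyxy[keep])[0]
            ok = bool((ious <= iou_threshold).all())
        if ok:
            keep.append(i)
    return [order[i] for i in keep]


def decode_and_nms(raw, cfg, conf_threshold: float = 0.25,
                   iou_threshold: float = 0.5) -> list[list[BoundingBox]]:
    """Full post-processing: decode, confidence filter, NMS; one box list
    per batch image."""
    if not 0 <= conf_threshold <= 1 or not 0 <= iou_threshold <= 1:
        raise ValueError("thresholds must lie in [0, 1]")
    out = []
    for cand in decode_raw(raw, cfg):
        cand = [b for b in cand if (b.confidence or 0) >= conf_threshold]
        out.append(nms(cand, iou_threshold))
    return out


# ---------------------------------------------------------------------------
# Matching and point metrics
# ---------------------------------------------------------------------------


def match_detections(preds: list[BoundingBox], gts: list[BoundingBox],
                     iou_threshold: float = 0.5) -> EvalCounts:
    """Greedy confidence-ordered matching: each prediction claims its
    best-overlap unmatched ground truth if the IoU clears the threshold
    (TP), else counts as FP; leftover ground truths are FN."""
    preds = sorted(preds, key=lambda b: -(b.confidence or 0.0))
    matched = _greedy_match_flags(preds, gts, iou_threshold)
    tp = int(matched.sum())
    return EvalCounts(tp=tp, fp=len(preds) - tp, fn=len(gts) - tp)


def _greedy_match_flags(preds, gts, iou_threshold) -> np.ndarray:
    """TP flag per prediction (assumed sorted by descending confidence)."""
    flags = np.zeros(len(preds), dtype=bool)
    if not preds or not gts:
        return flags
    pm = np.array([p.to_xyxy() for p in preds])
    gm = np.array([g.to_xyxy() for g in gts])
    ious = iou_matrix(pm, gm)
    used = np.zeros(len(gts), dtype=bool)
    for i in range(len(preds)):
        row = np.where(used, -1.0, ious[i])
        j = int(row.argmax())
        if row[j] >= iou_threshold:
            flags[i] = True
            used[j] = True
    return flags


def precision_recall_f1(counts: EvalCounts) -> tuple[float, float, float]:
    """Precision, recall and their harmonic mean; 0/0 defined as 0."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


# ---------------------------------------------------------------------------
# Average precision
# ---------------------------------------------------------------------------


def average_precision(preds: list[list[BoundingBox]],
                      gts: list[list[BoundingBox]],
                      iou_threshold: float = 0.5,
                      interpolation: str = "all") -> float:
    """AP over an image set at one IoU threshold.

    ``preds``/``gts`` are per-image box lists.  Predictions are pooled and
    ranked by confidence; TP/FP flags come from per-image greedy matching
    in that order.  The default integration is all-point interpolation
    (area under the precision envelope); ``interpolation='11point'``
    averages interpolated precision at recalls 0, 0.1, ..., 1.
    """
    n_gt = sum(len(g) for g in gts)
    if n_gt == 0:
        raise ValueError("average precision undefined with zero ground truths")
    rows = []  # (confidence, image index, pred)
    for img, plist in enumerate(preds):
        for p in plist:
            rows.append((-(p.confidence or 0.0), img, p))
    if not rows:
        return 0.0
    rows.sort(key=lambda t: t[0])
    per_img_sorted: dict[int, list[BoundingBox]] = {}
    for _, img, p in rows:
        per_img_sorted.setdefault(img, []).append(p)
    flags_by_img = {img: iter(_greedy_match_flags(ps, gts[img], iou_threshold))
                    for img, ps in per_img_sorted.items()}
    tp_flags = np.array([next(flags_by_img[img]) for _, img, _ in rows])
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(~tp_flags)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    if interpolation == "11point":
        ap = 0.0
        for r in np.linspace(0, 1, 11):
            mask = recall >= r
            ap += (precision[mask].max() if mask.any() else 0.0) / 11
        return float(ap)
    # all-point: integrate the running-max precision envelope over recall
    mrec = np.concatenate(([0.0], recall, [1.0]))
    mpre = np.concatenate(([1.0], precision, [0.0]))
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    idx = np.nonzero(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def ap50_95(preds, gts, interpolation: str = "all") -> float:
    """Mean AP over the ten IoU thresholds 0.50, 0.55, ..., 0.95."""
    return float(np.mean([average_precision(preds, gts, t, interpolation)
                          for t in AP_THRESHOLDS]))


# ---------------------------------------------------------------------------
# Aggregate + stratified evaluation
# ---------------------------------------------------------------------------


def evaluate(preds, gts, conf_threshold: float = 0.25,
             iou_threshold: float = 0.5) -> EvalResult:
    """Point metrics at the operating threshold plus AP50/AP50:95 over an
    image set."""
    tp = fp = fn = 0
    for p, g in zip(preds, gts):
        pc = [b for b in p if (b.confidence or 0) >= conf_threshold]
        c = match_detections(pc, g, iou_threshold)
        tp, fp, fn = tp + c.tp, fp + c.fp, fn + c.fn
    prec, rec, f1 = precision_recall_f1(EvalCounts(tp, fp, fn))
    n_gt = sum(len(g) for g in gts)
    if n_gt:
        a50 = average_precision(preds, gts, 0.5)
        a5095 = ap50_95(preds, gts)
    else:
        a50 = a5095 = None
    return EvalResult(prec, rec, f1, a50, a5095, n_gt,
                      sum(len(p) for p in preds))


def _pred_stratum(pred, gts_in_image, axis, image_size, iou_threshold):
    """Stratum of one prediction: its matched ground truth's stratum, or —
    unmatched — its own size class / its image-level tag."""
    if gts_in_image:
        pm = np.array([pred.to_xyxy()])
        gm = np.array([g.to_xyxy() for g in gts_in_image])
        ious = iou_matrix(pm, gm)[0]
        j = int(ious.argmax())
        if ious[j] >= iou_threshold:
            g = gts_in_image[j]
            return (size_class(g, image_size) if axis == "size"
                    else (g.tags or {}).get(axis))
    if axis == "size":
        return size_class(pred, image_size)
    return (pred.tags or {}).get(axis)


def stratified_eval(preds, gts, axis: str, image_size: int,
                    conf_threshold: float = 0.25, iou_threshold: float = 0.5
                    ) -> dict[str, EvalResult]:
    """Evaluation per stratum along ``axis`` ('size', or a tag key such as
    'illumination' / 'viewpoint').

    For the size axis, omitted-size boxes are excluded from both sides.
    Detections are assigned to the stratum of their matched ground truth;
    unmatched detections to their own stratum.
    """
    if axis == "size":
        strata = [s for s in ("small", "medium", "large")]
        gt_of = lambda g: size_class(g, image_size)  # noqa: E731
    else:
        strata = sorted({(g.tags or {}).get(axis)
                         for gl in gts for g in gl} - {None})
        gt_of = lambda g: (g.tags or {}).get(axis)  # noqa: E731

    out: dict[str, EvalResult] = {}
    for stratum in strata:
        sub_gts, sub_preds = [], []
        for plist, glist in zip(preds, gts):
            gsel = [g for g in glist if gt_of(g) == stratum]
            g_eval = ([g for g in glist if gt_of(g) != "omitted"]
                      if axis == "size" else glist)
            psel = [p for p in plist
                    if _pred_stratum(p, g_eval, axis, image_size,
                                     iou_threshold) == stratum]
            sub_gts.append(gsel)
            sub_preds.append(psel)
        if sum(len(g) for g in sub_gts) == 0:
            continue  # empty stratum reported as absent
        out[stratum] = evaluate(sub_preds, sub_gts, conf_threshold,
                                iou_threshold)
    return out


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def result_table(results: dict[str, EvalResult]) -> tuple[str, str]:
    """Render stratified results as (CSV text, JSON text) with AP50,
    AP50:95 and F1 columns per stratum."""
    buf = io.StringIO()
    wr = csv.writer(buf)
    wr.writerow(["stratum", "ap50", "ap50_95", "f1", "precision", "recall",
                 "n_gt", "n_pred"])
    payload = {}
    for name, r in results.items():
        wr.writerow([name,
                     "" if r.ap50 is None else f"{r.ap50:.4f}",
                     "" if r.ap50_95 is None else f"{r.ap50_95:.4f}",
                     f"{r.f1:.4f}", f"{r.precision:.4f}", f"{r.recall:.4f}",
                     r.n_gt, r.n_pred])
        payload[name] = dataclasses.asdict(r)
    return buf.getvalue(), json.dumps(payload, indent=2)
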