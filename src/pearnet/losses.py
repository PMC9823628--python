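"""Box overlap, the EIoU border-regression loss, and the composite
detection training loss.

The border loss replaces the more common CIoU term: on top of ``1 - IoU``
it penalises the squared center distance and the squared width and height
differences, each normalised by the corresponding extent of the smallest
enclosing box:

    L_EIoU = 1 - IoU
           + rho^2(b, b_gt) / c^2
           + (w - w_gt)^2 / C_w^2
           + (h - h_gt)^2 / C_h^2

where c is the enclosing-box diagonal and C_w, C_h its width and height.
The loss is zero iff the boxes coincide and is invariant to joint
translation and joint scaling of the pair.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .nn import Tensor
from .data_io import BoundingBox

__all__ = ["iou", "eiou_loss", "iou_matrix", "DetectionLoss", "detection_loss",
           "BoxPairGeometry"]

EPS = 1e-7


# ---------------------------------------------------------------------------
# Geometry on plain boxes
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class BoxPairGeometry:
    """All geometric quantities entering IoU/EIoU for one box pair
    (pixel units, or any common unit)."""

    area_pred: float
    area_gt: float
    intersection: float
    union: float
    center_dist_sq: float
    enclose_w: float
    enclose_h: float
    dw_sq: float
    dh_sq: float

    @property
    def enclose_diag_sq(self) -> float:
        return self.enclose_w ** 2 + self.enclose_h ** 2

    @classmethod
    def from_boxes(cls, pred: BoundingBox, gt: BoundingBox) -> "BoxPairGeometry":
        px1, py1, px2, py2 = pred.to_xyxy()
        gx1, gy1, gx2, gy2 = gt.to_xyxy()
        iw = max(min(px2, gx2) - max(px1, gx1), 0.0)
        ih = max(min(py2, gy2) - max(py1, gy1), 0.0)
        inter = iw * ih
        ap, ag = pred.area, gt.area
        return cls(
            area_pred=ap, area_gt=ag, intersection=inter,
            union=ap + ag - inter,
            center_dist_sq=(pred.cx - gt.cx) ** 2 + (pred.cy - gt.cy) ** 2,
            enclose_w=max(px2, gx2) - min(px1, gx1),
            enclose_h=max(py2, gy2) - min(py1, gy1),
            dw_sq=(pred.w - gt.w) ** 2, dh_sq=(pred.h - gt.h) ** 2,
        )


def iou(box_a: BoundingBox, box_b: BoundingBox) -> float:
    """Intersection over union of two boxes, in [0, 1]; 0 for a degenerate
    zero-area pair."""
    g = BoxPairGeometry.from_boxes(box_a, box_b)
    if g.union <= 0.0:
        return 0.0
    return g.intersection / g.union


def eiou_loss(pred: BoundingBox, gt: BoundingBox) -> float:
    """EIoU border loss for one box pair; >= 0, zero iff the boxes coincide."""
    g = BoxPairGeometry.from_boxes(pred, gt)
    if g.enclose_w <= 0.0 and g.enclose_h <= 0.0:
        return 0.0  # both boxes degenerate at one point
    i = g.intersection / g.union if g.union > 0 else 0.0
    return (1.0 - i
            + g.center_dist_sq / (g.enclose_diag_sq + EPS)
            + g.dw_sq / (g.enclose_w ** 2 + EPS)
            + g.dh_sq / (g.enclose_h ** 2 + EPS))


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between boxes ``a`` (N, 4) and ``b`` (M, 4) in
    xyxy layout."""
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    x1 = np.maximum(a[:, None, 0], b[None, :, 0])
    y1 = np.maximum(a[:, None, 1], b[None, :, 1])
    x2 = np.minimum(a[:, None, 2], b[None, :, 2])
    y2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(x2 - x1, 0, None) * np.clip(y2 - y1, 0, None)
    aa = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    ab = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = aa[:, None] + ab[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, EPS), 0.0)


# ---------------------------------------------------------------------------
# Differentiable EIoU on decoded predictions
# ---------------------------------------------------------------------------


def _eiou_tensor(pred: Tensor, gt: np.ndarray) -> tuple[Tensor, np.ndarray]:
    """EIoU per row for predicted boxes (Tensor (N, 4) cx cy w h, grid
    units) against constant ground truth (N, 4).  Returns the per-row loss
    Tensor and the detached IoU values (used as objectness targets)."""
    pcx, pcy, pw, ph = pred[:, 0], pred[:, 1], pred[:, 2], pred[:, 3]
    gcx, gcy, gw, gh = gt[:, 0], gt[:, 1], gt[:, 2], gt[:, 3]
    px1, px2 = pcx - pw * 0.5, pcx + pw * 0.5
    py1, py2 = pcy - ph * 0.5, pcy + ph * 0.5
    gx1, gx2 = gcx - gw * 0.5, gcx + gw * 0.5
    gy1, gy2 = gcy - gh * 0.5, gcy + gh * 0.5
    iw = (px2.minimum(gx2) - px1.maximum(gx1)).maximum(0.0)
    ih = (py2.minimum(gy2) - py1.maximum(gy1)).maximum(0.0)
    inter = iw * ih
    union = pw * ph + gw * gh - inter + EPS
    iou_t = inter / union
    cw = px2.maximum(gx2) - px1.minimum(gx1)
    ch = py2.maximum(gy2) - py1.minimum(gy1)
    c2 = cw * cw + ch * ch + EPS
    rho2 = (pcx - gcx) ** 2.0 + (pcy - gcy) ** 2.0
    loss = (1.0 - iou_t + rho2 / c2
            + (pw - gw) ** 2.0 / (cw * cw + EPS)
            + (ph - gh) ** 2.0 / (ch * ch + EPS))
    return loss, np.clip(iou_t.data.copy(), 0.0, 1.0)


# ---------------------------------------------------------------------------
# Composite detection loss
# ---------------------------------------------------------------------------

_NEIGHBOR_BIAS = 0.5
_OBJ_BALANCE = (4.0, 1.0, 0.4)  # per-scale objectness weights (8/16/32)


class DetectionLoss:
    """Composite loss for the three-scale anchor head.

    total = w_box * mean EIoU  +  w_obj * BCE(objectness)
          + w_cls * BCE(class)

    Targets are assigned by the stock multi-anchor rule: a target matches
    every anchor whose width/height ratio to the target is within
    ``anchor_t`` (4.0), in its own grid cell plus the two adjacent cells
    nearest to the box center.  Objectness targets at assigned positions
    are the detached IoU of the decoded prediction.  The class term is
    trained toward 1 for the (single) pear class.
    """

    def __init__(self, cfg, w_box: float = 0.05, w_obj: float = 1.0,
                 w_cls: float = 0.5, anchor_t: float = 4.0):
        self.cfg = cfg
        self.w_box, self.w_obj, self.w_cls = w_box, w_obj, w_cls
        self.anchor_t = anchor_t
        self.strides = (8, 16, 32)

    def build_targets(self, targets: list[list[BoundingBox]], grids):
        """Per-scale assignment: returns for each scale arrays
        (b, a, gj, gi, gt_box_grid_units (n,4))."""
        anchors_px = self.cfg.scaled_anchors()  # (3, 3, 2)
        out = []
        for si, (gh, gw) in enumerate(grids):
            stride = self.cfg.input_size / gw
            anchors_g = anchors_px[si] / stride  # grid units
            bs, as_, gjs, gis, gts, ancs = [], [], [], [], [], []
            for bi, boxes in enumerate(targets):
                for box in boxes:
                    t = np.array([box.cx * gw, box.cy * gh,
                                  box.w * gw, box.h * gh])
                    if t[2] <= 0 or t[3] <= 0:
                        continue
                    for ai, (aw, ah) in enumerate(anchors_g):
                        r = max(t[2] / aw, aw / t[2], t[3] / ah, ah / t[3])
                        if r >= self.anchor_t:
                            continue
                        gi0, gj0 = int(t[0]), int(t[1])
                        cells = [(gi0, gj0)]
                        fx, fy = t[0] - gi0, t[1] - gj0
                        if fx < _NEIGHBOR_BIAS and gi0 > 0:
                            cells.append((gi0 - 1, gj0))
                        elif fx >= 1 - _NEIGHBOR_BIAS and gi0 < gw - 1:
                            cells.append((gi0 + 1, gj0))
                        if fy < _NEIGHBOR_BIAS and gj0 > 0:
                            cells.append((gi0, gj0 - 1))
                        elif fy >= 1 - _NEIGHBOR_BIAS and gj0 < gh - 1:
                            cells.append((gi0, gj0 + 1))
                        for gi, gj in cells:
                            bs.append(bi); as_.append(ai)
                            gjs.append(min(max(gj, 0), gh - 1))
                            gis.append(min(max(gi, 0), gw - 1))
                            gts.append(t); ancs.append(anchors_g[ai])
            out.append((np.array(bs, dtype=int), np.array(as_, dtype=int),
                        np.array(gjs, dtype=int), np.array(gis, dtype=int),
                        np.array(gts).reshape(-1, 4),
                        np.array(ancs).reshape(-1, 2)))
        return out

    def __call__(self, raw: list[Tensor], targets: list[list[BoundingBox]]
                 ) -> tuple[Tensor, dict[str, float]]:
        grids = [t.shape[2:4] for t in raw]
        assigned = self.build_targets(targets, grids)
        box_terms, cls_terms = [], []
        obj_loss = None
        n_assigned = 0
        for si, (p, (b, a, gj, gi, gt, anc)) in enumerate(zip(raw, assigned)):
            n, na, gh, gw, _ = p.shape
            obj_target = np.zeros((n, na, gh, gw), dtype=np.float32)
            if len(b):
                n_assigned += len(b)
                sel = p[b, a, gj, gi]               # (k, 5+nc)
                xy = sel[:, 0:2].sigmoid() * 2.0 - 0.5
                wh = (sel[:, 2:4].sigmoid() * 2.0) ** 2.0 * anc
                cell = np.stack([gi, gj], axis=1).astype(np.float32)
                pbox = nn.concat([xy + cell, wh], axis=1)
                eiou, iou_det = _eiou_tensor(pbox, gt)
                box_terms.append(eiou.mean())
                np.maximum.at(obj_target, (b, a, gj, gi),
                              iou_det.astype(np.float32))
                if self.cfg.num_classes >= 1:
                    cls_logits = sel[:, 5:]
                    cls_target = np.zeros(cls_logits.shape, dtype=np.float32)
                    cls_target[np.arange(len(b)), 0] = 1.0  # single class
                    cls_terms.append(nn.bce_with_logits(cls_logits, cls_target))
            term = nn.bce_with_logits(p[..., 4], obj_target) * _OBJ_BALANCE[si]
            obj_loss = term if obj_loss is None else obj_loss + term
        nb = max(len(raw[0].data), 1)
        box_loss = (sum(box_terms[1:], box_terms[0]) * (1.0 / len(box_terms))
                    if box_terms else Tensor(0.0))
        cls_loss = (sum(cls_terms[1:], cls_terms[0]) * (1.0 / len(cls_terms))
                    if cls_terms else Tensor(0.0))
        total = (self.w_box * box_loss + self.w_obj * obj_loss
                 + self.w_cls * cls_loss) * float(nb)
        comps = {"box": float(box_loss.data), "obj": float(obj_loss.data),
                 "cls": float(cls_loss.data), "total": float(total.data),
                 "n_assigned": n_assigned}
        return total, comps


def detection_loss(raw, targets, cfg, weights=(0.05, 1.0, 0.5)):
    """Functional wrapper around :class:`DetectionLoss`."""
    return DetectionLoss(cfg, *weights)(raw, targets)
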