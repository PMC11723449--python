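"""Target assignment and the composite detection loss.

Assignment is anchor-free and deterministic: each ground-truth box goes to
the cell containing its centre, at the finest stride whose distribution-
focal range (REG_MAX - 1 bins per side) can represent the box; when two
boxes claim one cell the smaller box wins (ties broken by coordinates), so
the result is invariant to the order in which boxes are listed.

The loss is the YOLO-family composite: binary cross-entropy over category
logits (optionally perturbed by the prediction balance module while
training), complete-IoU on decoded boxes, and a distribution-focal
cross-entropy on the two bins adjacent to each true distance, weighted
7.5 / 0.5 / 1.5 (box / cls / dfl).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .model import REG_MAX
from .pbm import VariationVector

LOSS_WEIGHTS = {"box": 7.5, "cls": 0.5, "dfl": 1.5}


@dataclass
class ScaleAssignment:
    pos_cells: np.ndarray      # (P,) flat cell indices
    pos_imgs: np.ndarray       # (P,) image index within batch
    target_cat: np.ndarray     # (P,)
    target_ltrb: np.ndarray    # (P, 4) distances in stride units, >= 0
    cls_target: np.ndarray     # (N, h*w, nc) one-hot map


@dataclass
class Assignments:
    scales: list
    n_pos: int
    shapes: list = field(default_factory=list)


def assign_targets(gt_per_image, grid_shapes, strides, n_categories) -> Assignments:
    """gt_per_image: list over batch of (boxes_xyxy_px (n,4), cats (n,)).

    Returns positive-cell assignments per scale; every ground-truth box is
    assigned to exactly one cell unless another, smaller box claims the same
    cell.  Background cells carry classification targets of zero only.
    """
    n_img = len(gt_per_image)
    cell_owner = [dict() for _ in grid_shapes]  # (img, cell) -> (area, key, cat, ltrb)
    for img_i, (boxes, cats) in enumerate(gt_per_image):
        boxes = np.asarray(boxes, np.float32).reshape(-1, 4)
        cats = np.asarray(cats, np.int64).reshape(-1)
        order = sorted(
            range(len(boxes)),
            key=lambda i: (-(boxes[i, 2] - boxes[i, 0]) * (boxes[i, 3] - boxes[i, 1]),
                           boxes[i, 0], boxes[i, 1], cats[i]))
        for i in order:  # descending area: smaller boxes overwrite later
            x0, y0, x1, y1 = boxes[i]
            cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
            chosen = len(strides) - 1
            for si, s in enumerate(strides):
                half = max(x1 - x0, y1 - y0) / 2 / s
                if half <= REG_MAX - 1.5:  # representable with margin
                    chosen = si
                    break
            s = strides[chosen]
            h, w = grid_shapes[chosen]
            gx = min(int(cx // s), w - 1)
            gy = min(int(cy // s), h - 1)
            ccx, ccy = (gx + 0.5) * s, (gy + 0.5) * s
            ltrb = np.array([ccx - x0, ccy - y0, x1 - ccx, y1 - ccy], np.float32) / s
            if (ltrb < 0).any():
                ltrb = np.clip(ltrb, 0.01, None)
            cell_owner[chosen][(img_i, gy * w + gx)] = (int(cats[i]), ltrb)
    scales = []
    n_pos = 0
    for si, (h, w) in enumerate(grid_shapes):
        items = sorted(cell_owner[si].items())
        pos_imgs = np.array([k[0] for k, _ in items], np.int64)
        pos_cells = np.array([k[1] for k, _ in items], np.int64)
        target_cat = np.array([v[0] for _, v in items], np.int64)
        target_ltrb = (np.stack([v[1] for _, v in items])
                       if items else np.zeros((0, 4), np.float32))
        cls_target = np.zeros((n_img, h * w, n_categories), np.float32)
        cls_target[pos_imgs, pos_cells, target_cat] = 1.0
        scales.append(ScaleAssignment(pos_cells, pos_imgs, target_cat,
                                      target_ltrb, cls_target))
        n_pos += len(items)
    return Assignments(scales=scales, n_pos=n_pos, shapes=list(grid_shapes))


def _bce_with_logits_sum(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Numerically stable sum of elementwise BCE-with-logits."""
    t = Tensor(targets)
    loss = ag.maximum(logits, 0.0) - logits * t + ag.log(ag.exp(-ag.absolute(logits)) + 1.0)
    return loss.sum()


def _ciou_loss(pred_ltrb: Tensor, target_ltrb: np.ndarray) -> Tensor:
    """Mean complete-IoU loss between boxes given as centre distances
    (l, t, r, b) in a shared frame (the cell centre is the origin)."""
    tl, tt, tr, tb = (Tensor(target_ltrb[:, i]) for i in range(4))
    pl, pt, pr, pb = (pred_ltrb[:, i] for i in range(4))
    iw = ag.maximum(ag.minimum(pr, tr) + ag.minimum(pl, tl), 0.0)
    ih = ag.maximum(ag.minimum(pb, tb) + ag.minimum(pt, tt), 0.0)
    inter = iw * ih
    area_p = ag.maximum(pl + pr, 1e-6) * ag.maximum(pt + pb, 1e-6)
    area_t = (tl + tr) * (tt + tb)
    union = area_p + area_t - inter + 1e-7
    iou = inter / union
    # centre distance over enclosing-box diagonal
    dcx = (pr - pl) * 0.5 - (tr - tl) * 0.5
    dcy = (pb - pt) * 0.5 - (tb - tt) * 0.5
    cw = ag.maximum(pr, tr) + ag.maximum(pl, tl)
    chh = ag.maximum(pb, tb) + ag.maximum(pt, tt)
    c2 = cw * cw + chh * chh + 1e-7
    rho2 = dcx * dcx + dcy * dcy
    wp = ag.maximum(pl + pr, 1e-6)
    hp = ag.maximum(pt + pb, 1e-6)
    v = (4.0 / np.pi ** 2) * (ag.atan((tl + tr) / (tt + tb)) - ag.atan(wp / hp)) ** 2
    alpha = Tensor(v.data / (1.0 - iou.data + v.data + 1e-7))  # detached
    return (1.0 - iou + rho2 / c2 + alpha * v).mean()


def _dfl_loss(pred_bins: Tensor, target: np.ndarray) -> Tensor:
    """Cross-entropy against the two integer bins bracketing each distance.
    pred_bins: (P, 4, REG_MAX) logits; target: (P, 4) in [0, REG_MAX-1]."""
    t = np.clip(target, 0.0, REG_MAX - 1.001)
    lo = np.floor(t).astype(np.int64)
    w_hi = (t - lo).astype(np.float32)
    w_lo = 1.0 - w_hi
    p = ag.softmax(pred_bins, axis=2)
    idx0, idx1 = np.indices(t.shape)
    p_lo = p[idx0, idx1, lo]
    p_hi = p[idx0, idx1, np.minimum(lo + 1, REG_MAX - 1)]
    nll = -(Tensor(w_lo) * ag.log(p_lo + 1e-9) + Tensor(w_hi) * ag.log(p_hi + 1e-9))
    return nll.mean()


def compute_loss(outputs, assignments: Assignments,
                 pbm_state: VariationVector | None = None,
                 training: bool = True):
    """Composite detection loss.

    Returns (total_loss Tensor, components dict of floats).  The class
    logits are shifted by the current perturbation vector only while
    training with the balance module enabled.
    """
    n_pos = max(assignments.n_pos, 1)
    cls_sum = None
    box_terms, dfl_terms = [], []
    for (cls, reg), sa in zip(outputs, assignments.scales):
        n, nc, h, w = cls.shape
        logits = cls.transpose(0, 2, 3, 1).reshape((n, h * w, nc))
        if training and pbm_state is not None:
            logits = logits + Tensor(pbm_state.variation.astype(np.float32))
        if not np.isfinite(logits.data).all():
            raise FloatingPointError("non-finite classification logits")
        term = _bce_with_logits_sum(logits, sa.cls_target)
        cls_sum = term if cls_sum is None else cls_sum + term
        if len(sa.pos_cells) == 0:
            continue
        regs = reg.transpose(0, 2, 3, 1).reshape((n, h * w, 4, REG_MAX))
        pos = regs[sa.pos_imgs, sa.pos_cells]               # (P, 4, REG_MAX)
        if not np.isfinite(pos.data).all():
            raise FloatingPointError("non-finite box regression logits")
        bins = Tensor(np.arange(REG_MAX, dtype=np.float32))
        pred_ltrb = (ag.softmax(pos, axis=2) * bins).sum(axis=2)  # (P, 4)
        box_terms.append((_ciou_loss(pred_ltrb, sa.target_ltrb), len(sa.pos_cells)))
        dfl_terms.append((_dfl_loss(pos, sa.target_ltrb), len(sa.pos_cells)))
    cls_loss = cls_sum * (1.0 / n_pos)
    if box_terms:
        tot = sum(n for _, n in box_terms)
        box_loss = sum((t * (n / tot) for t, n in box_terms), Tensor(0.0))
        dfl_loss = sum((t * (n / tot) for t, n in dfl_terms), Tensor(0.0))
    else:
        box_loss = Tensor(0.0)
        dfl_loss = Tensor(0.0)
    total = (LOSS_WEIGHTS["box"] * box_loss + LOSS_WEIGHTS["cls"] * cls_loss
             + LOSS_WEIGHTS["dfl"] * dfl_loss)
    comps = {"box": float(box_loss.data), "cls": float(cls_loss.data),
             "dfl": float(dfl_loss.data), "total": float(total.data)}
    return total, comps
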