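"""Detection metrics: IoU matching, precision/recall, per-category average
precision and mAP aggregates.

AP is the literal rank summation  AP = sum_n (R_n - R_{n-1}) * P_n  over
detections ordered by descending confidence (no interpolation); a COCO-style
101-point interpolated variant is available behind a flag for cross-checks.
mAP is the arithmetic mean of per-category AP; categories with no ground
truth are excluded from the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

IOU_50_95 = tuple(round(0.5 + 0.05 * i, 2) for i in range(10))


@dataclass(frozen=True)
class MatchCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class MetricReport:
    """Per-category AP at each IoU threshold plus mAP aggregates (fractions
    in [0, 1]; callers multiply by 100 for table-style percentages)."""
    ap: dict              # {iou_threshold: {category: AP}}
    map50: float | None
    map75: float | None
    map50_95: float | None
    precision: float | None = None
    recall: float | None = None
    f1_confidence: float | None = None
    n_ground_truth: dict = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return self.map50 is not None


def iou(box_a, box_b) -> float:
    """Intersection over union of two half-open pixel boxes (x0, y0, x1, y1)."""
    ax0, ay0, ax1, ay1 = box_a
    bx0, by0, bx1, by1 = box_b
    if ax1 <= ax0 or ay1 <= ay0 or bx1 <= bx0 or by1 <= by0:
        raise ValueError("degenerate box")
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union


def match_detections(detections, ground_truth, iou_threshold: float):
    """Greedy one-to-one matching of same-category detections to ground truth.

    `detections`: (box, confidence) pairs; `ground_truth`: boxes.  Detections
    are processed in descending confidence; each is matched to the unmatched
    ground-truth box of highest IoU >= threshold (IoU ties broken by lower
    ground-truth index).  Returns (MatchCounts, per-detection TP flags in
    confidence order).
    """
    order = sorted(range(len(detections)), key=lambda i: -detections[i][1])
    matched = [False] * len(ground_truth)
    flags = np.zeros(len(detections), dtype=bool)
    for rank, i in enumerate(order):
        box = detections[i][0]
        best, best_iou = -1, iou_threshold
        for j, gt in enumerate(ground_truth):
            if matched[j]:
                continue
            v = iou(box, gt)
            if v > best_iou or (v == best_iou and v > 0 and best == -1):
                best, best_iou = j, v
        if best >= 0:
            matched[best] = True
            flags[rank] = True
    tp = int(flags.sum())
    counts = MatchCounts(tp=tp, fp=len(detections) - tp,
                         fn=len(ground_truth) - tp)
    return counts, flags


def precision_recall(counts: MatchCounts):
    """P = TP/(TP+FP), R = TP/(TP+FN); zero by convention on empty denominators."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    return p, r


def pr_curve(flags, n_ground_truth: int):
    """Accumulate ranked TP flags into (R_n, P_n) points."""
    if n_ground_truth < 0:
        raise ValueError("n_ground_truth must be >= 0")
    flags = np.asarray(flags, dtype=float)
    tp = np.cumsum(flags)
    n = np.arange(1, len(flags) + 1)
    precision = tp / n
    recall = tp / n_ground_truth if n_ground_truth else np.zeros_like(tp)
    return np.stack([recall, precision], axis=1)


def average_precision(curve: np.ndarray, interpolated_101: bool = False) -> float:
    """AP = sum_n (R_n - R_{n-1}) P_n over the ranked curve (R_0 = 0).

    With `interpolated_101`, evaluate max precision at 101 evenly spaced
    recall points instead (COCO style) — used only for cross-checking.
    """
    if len(curve) == 0:
        return 0.0
    recall, precision = curve[:, 0], curve[:, 1]
    if interpolated_101:
        prec_env = np.maximum.accumulate(precision[::-1])[::-1]
        pts = np.linspace(0, 1, 101)
        idx = np.searchsorted(recall, pts, side="left")
        vals = np.where(idx < len(prec_env), prec_env[np.minimum(idx, len(prec_env) - 1)], 0.0)
        return float(vals.mean())
    prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev) * precision))


def evaluate(detections_per_image, ground_truth_per_image,
             iou_thresholds=IOU_50_95, conf_threshold=None) -> MetricReport:
    """Full evaluation over a set of images.

    `detections_per_image`: list (one entry per image) of lists of
    (category, confidence, box); `ground_truth_per_image`: list of lists of
    (category, box).  Categories never seen in the ground truth are excluded
    from every mean; if there is no ground truth at all the report's mAP
    fields are None (flagged, not silently zero).
    """
    cats = sorted({c for gts in ground_truth_per_image for c, _ in gts})
    n_gt = {k: sum(1 for gts in ground_truth_per_image for c, _ in gts if c == k)
            for k in cats}
    ap: dict = {t: {} for t in iou_thresholds}
    for k in cats:
        # gather this category's detections across images, ranked globally
        per_img_det = [[(b, s) for c, s, b in dets if c == k]
                       for dets in detections_per_image]
        per_img_gt = [[b for c, b in gts if c == k] for gts in ground_truth_per_image]
        for t in iou_thresholds:
            recs = []  # (confidence, tp_flag)
            for dets, gts in zip(per_img_det, per_img_gt):
                if not dets:
                    continue
                _, flags = match_detections(dets, gts, t)
                confs = sorted((s for _, s in dets), reverse=True)
                recs.extend(zip(confs, flags))
            recs.sort(key=lambda r: -r[0])
            curve = pr_curve([f for _, f in recs], n_gt[k])
            ap[t][k] = average_precision(curve)
    if not cats:
        return MetricReport(ap=ap, map50=None, map75=None, map50_95=None)

    def mean_ap(t):
        return float(np.mean([ap[t][k] for k in cats])) if t in ap else None

    map50 = mean_ap(0.5)
    map75 = mean_ap(0.75)
    per_t = [mean_ap(t) for t in iou_thresholds]
    map50_95 = float(np.mean(per_t)) if len(iou_thresholds) == 10 else None

    report = MetricReport(ap=ap, map50=map50, map75=map75, map50_95=map50_95,
                          n_ground_truth=n_gt)
    _micro_pr(report, detections_per_image, ground_truth_per_image, cats,
              conf_threshold)
    return report


def _micro_pr(report, dets_per_img, gts_per_img, cats, conf_threshold):
    """Micro precision/recall at a fixed confidence, or at the F1-optimal
    confidence when none is given (the threshold is recorded either way)."""
    thresholds = ([conf_threshold] if conf_threshold is not None else
                  sorted({s for dets in dets_per_img for _, s, _ in dets},
                         reverse=True) or [0.5])
    best = (-1.0, 0.0, 0.0, 0.5)
    for thr in thresholds:
        tp = fp = fn = 0
        for dets, gts in zip(dets_per_img, gts_per_img):
            for k in cats:
                d = [(b, s) for c, s, b in dets if c == k and s >= thr]
                g = [b for c, b in gts if c == k]
                counts, _ = match_detections(d, g, 0.5)
                tp += counts.tp
                fp += counts.fp
                fn += counts.fn
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        if f1 > best[0]:
            best = (f1, p, r, thr)
    _, report.precision, report.recall, report.f1_confidence = best
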