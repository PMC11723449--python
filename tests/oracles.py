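"""Independent brute-force reference implementations used only by tests.

Everything here is written directly from first principles (explicit loops,
no shared code with the package) so it can serve as an oracle.
"""

import numpy as np


def box_iou(a, b):
    ix0, iy0 = max(a[0], b[0]), max(a[1], b[1])
    ix1, iy1 = min(a[2], b[2]), min(a[3], b[3])
    if ix1 <= ix0 or iy1 <= iy0:
        return 0.0
    inter = (ix1 - ix0) * (iy1 - iy0)
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def evaluate_bruteforce(dets_per_img, gts_per_img, thresholds):
    """Exhaustive re-implementation of category-wise AP and mAP.

    Greedy confidence-ordered matching to the unmatched ground truth of
    highest IoU (ties by lower index), per-image; ranked globally; AP by the
    literal rank summation sum_n (R_n - R_{n-1}) * P_n.
    """
    cats = sorted({c for gts in gts_per_img for c, _ in gts})
    ap = {t: {} for t in thresholds}
    for t in thresholds:
        for k in cats:
            n_gt = sum(1 for gts in gts_per_img for c, _ in gts if c == k)
            records = []  # (confidence, is_tp)
            for dets, gts in zip(dets_per_img, gts_per_img):
                d = sorted([(s, b) for c, s, b in dets if c == k],
                           key=lambda r: -r[0])
                g = [b for c, b in gts if c == k]
                used = [False] * len(g)
                for s, b in d:
                    best_j, best_v = -1, t
                    for j in range(len(g)):
                        if used[j]:
                            continue
                        v = box_iou(b, g[j])
                        if v >= t and v > best_v or (v == best_v and v >= t and best_j == -1):
                            best_j, best_v = j, v
                    if best_j >= 0:
                        used[best_j] = True
                        records.append((s, True))
                    else:
                        records.append((s, False))
            records.sort(key=lambda r: -r[0])
            tp = 0
            prev_recall = 0.0
            total = 0.0
            for n, (_, is_tp) in enumerate(records, start=1):
                if is_tp:
                    tp += 1
                recall = tp / n_gt if n_gt else 0.0
                precision = tp / n
                total += (recall - prev_recall) * precision
                prev_recall = recall
            ap[t][k] = total
    means = {t: sum(ap[t].values()) / len(cats) if cats else None
             for t in thresholds}
    return ap, means


def random_scene(rng, n_cats=3, img=96, max_obj=5):
    """A random detection scene: ground truth plus noisy detections."""
    gts, dets = [], []
    for _ in range(rng.integers(1, max_obj + 1)):
        w, h = rng.integers(8, 32, size=2)
        x0 = rng.integers(0, img - w)
        y0 = rng.integers(0, img - h)
        cat = int(rng.integers(0, n_cats))
        gts.append((cat, (float(x0), float(y0), float(x0 + w), float(y0 + h))))
        # jittered detection, sometimes wrong category, sometimes missing
        if rng.random() < 0.85:
            j = rng.normal(0, 3, size=4)
            box = (float(x0 + j[0]), float(y0 + j[1]),
                   float(x0 + w + j[2]), float(y0 + h + j[3]))
            if box[2] > box[0] and box[3] > box[1]:
                c = cat if rng.random() < 0.8 else int(rng.integers(0, n_cats))
                dets.append((c, float(rng.random()), box))
    for _ in range(rng.integers(0, 3)):  # pure false positives
        w, h = rng.integers(8, 24, size=2)
        x0 = rng.integers(0, img - w)
        y0 = rng.integers(0, img - h)
        dets.append((int(rng.integers(0, n_cats)), float(rng.random()),
                     (float(x0), float(y0), float(x0 + w), float(y0 + h))))
    return dets, gts
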