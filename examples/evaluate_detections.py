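"""Average precision by the rank summation AP = sum_n (R_n - R_{n-1}) P_n.

A tiny worked scene: two species, three detections, two ground truths —
small enough to verify the precision/recall points by hand.
"""

from bsdnet import evaluate

ground_truth = [[(0, (10, 10, 30, 30)), (1, (50, 50, 70, 70))]]
detections = [[
    (0, 0.95, (11, 11, 31, 31)),    # good hit on the first bird
    (0, 0.60, (12, 9, 33, 28)),     # duplicate -> false positive
    (1, 0.80, (40, 40, 55, 55)),    # poor overlap -> miss
]]

report = evaluate(detections, ground_truth)
for cat, ap in sorted(report.ap[0.5].items()):
    print(f"category {cat}: AP50 = {ap:.4f}")
print(f"mAP50    = {report.map50 * 100:.2f}%")
print(f"mAP50:95 = {report.map50_95 * 100:.2f}%")
print(f"P = {report.precision:.2f}, R = {report.recall:.2f} "
      f"(at the F1-optimal confidence {report.f1_confidence})")

# Category 0: ranked flags [TP, FP] with 1 GT -> AP = 1.0; category 1: the
# only detection overlaps its GT below IoU 0.5 -> AP = 0; mAP50 = 50%.
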