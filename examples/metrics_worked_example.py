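"""Segmentation metrics on a 2x2 worked example, by hand and by the library.

Ground truth [[1,1],[0,0]] against prediction [[1,0],[0,0]] gives tp=1, fp=0,
fn=1, tn=2 — small enough to verify every formula mentally.
"""

import numpy as np

from dmffnet import bce_loss, confusion_counts, metrics_from_counts, poly_lr

gt = np.array([[1, 1], [0, 0]])
pred = np.array([[1, 0], [0, 0]])
c = confusion_counts(pred, gt)
print(f"counts: tp={c.tp} tn={c.tn} fp={c.fp} fn={c.fn}")
m = metrics_from_counts(c)
for key, value in m.items():
    print(f"  {key:10s}= {value:.4f}")
print("acc = 3/4; precision = 1 (no false alarms); recall = 1/2 (one missed "
      "lesion pixel); F1 = 2/3 their harmonic mean; MIoU = (1/2 + 2/3)/2 = 7/12.")

print(f"\nBCE of an uninformative p=0.5 on a positive pixel: "
      f"{bce_loss(np.array([0.5]), np.array([1.0])):.4f} (= ln 2)")
print(f"poly LR schedule: start {poly_lr(0, 1000):.4g}, "
      f"midpoint(power=1) {poly_lr(500, 1000, power=1.0):.4g}, "
      f"end {poly_lr(1000, 1000):.4g}")
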