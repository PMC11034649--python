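"""Evaluation metrics on small masks with known answers.

Dice/Jaccard count pixel overlap; HD95/ASD summarize boundary-to-boundary
Euclidean distances (in pixels, per 2D slice).
"""

import numpy as np

from plmt import asd, dice, hd95, jaccard

# |P| = |G| = 100 pixels with 50 overlapping -> Dice 0.5, Jaccard 1/3
pred = np.zeros((20, 20), dtype=bool)
gt = np.zeros((20, 20), dtype=bool)
pred.flat[:100] = True
gt.flat[50:150] = True
print(f"overlap 50/100/100: dice={dice(pred, gt):.4f} "
      f"jaccard={jaccard(pred, gt):.4f}")

# two single-pixel masks 5 pixels apart: every boundary distance is 5
a = np.zeros((8, 8), dtype=bool)
b = np.zeros((8, 8), dtype=bool)
a[0, 0] = True
b[3, 4] = True
print(f"single pixels at (0,0) and (3,4): hd95={hd95(a, b):.1f} "
      f"asd={asd(a, b):.1f} (3-4-5 triangle)")

# a square against itself shifted by one column: distances are 0 or 1
sq = np.zeros((8, 8), dtype=bool)
sq[2:5, 2:5] = True
shifted = np.roll(sq, 1, axis=1)
print(f"3x3 square vs 1-px shift: hd95={hd95(sq, shifted):.2f} "
      f"asd={asd(sq, shifted):.4f}")
print("identical masks score dice=1, distances 0; the empty/empty pair scores")
print("dice=1 by convention while surface distances are undefined and excluded.")
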