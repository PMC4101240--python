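"""Score a predicted segmentation against ground truth with MRMSE and Dice.

Builds a truth mask and a slightly shifted prediction, then evaluates both
metrics the same way the `vesselac evaluate` CLI does.
"""
import numpy as np

import vesselac as va

truth = np.zeros((60, 60), dtype=bool)
truth[20:40, 15:45] = True

shifted = np.zeros_like(truth)
shifted[21:41, 15:45] = True  # 1 px downward shift

print(f"Dice (identical)   : {va.dice(truth, truth):.3f}")
print(f"Dice (1 px shift)  : {va.dice(truth, shifted):.3f}")

res = va.mask_mrmse(truth, shifted, r=12)
print(f"MRMSE (1 px shift) : {res.value:.3f} px^2  "
      f"(k1={res.k1}, k2={res.k2}, k3={res.k3})")

empty = np.zeros_like(truth)
res_empty = va.mask_mrmse(truth, empty, r=12)
print(f"MRMSE (no contour) : {res_empty.value:.1f} px^2 = 2 r^2")

# MRMSE matches each truth boundary point to its nearest predicted point
# within a (2r+1)x(2r+1) window and averages the squared distances; points
# with no match on either side are charged the worst-case 2 r^2 penalty,
# so a missing prediction saturates at 288 for the standard r = 12.
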