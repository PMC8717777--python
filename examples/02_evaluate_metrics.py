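"""The SPES evaluation triplet on a pair of masks.

Dice measures overlap (1 is perfect); Hausdorff distance is the worst
surface-to-surface error in mm; ASSD is the average symmetric surface
distance in mm. Both distances use the 2 mm isotropic pixel spacing.
"""

import numpy as np

from colnet import assd, dice_coefficient, hausdorff_distance

truth = np.zeros((64, 64), np.uint8)
truth[20:35, 22:40] = 1                 # reference lesion

pred = np.zeros((64, 64), np.uint8)
pred[22:36, 24:40] = 1                  # slightly shifted prediction

dc = dice_coefficient(pred, truth)
hd = hausdorff_distance(pred, truth, spacing_mm=2.0)
sd = assd(pred, truth, spacing_mm=2.0)
print(f"DC   = {dc:.4f}   (overlap fraction, unitless)")
print(f"HD   = {hd:.2f} mm (worst-case boundary error)")
print(f"ASSD = {sd:.2f} mm (mean boundary error)")
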