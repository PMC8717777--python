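"""Generate a synthetic stroke-phantom dataset and inspect its structure.

Each case is a 6-channel 64x64 slice (2 mm spacing) with an elliptical
infarct core (dark on the DWI-like channel 0) inside a penumbra annulus
(bright on the Tmax-like channel 2); the annulus is the segmentation target.
"""

import numpy as np

from colnet import PhantomConfig, generate_dataset, split_dataset

config = PhantomConfig(n_cases=30, seed=7)
records = generate_dataset(config)

first = records[0]
mask = first.mask.values
print(f"generated {len(records)} cases, "
      f"image shape {first.image.values.shape}, "
      f"spacing {first.spacing_mm} mm")
print(f"case {first.case_id}: penumbra pixels = {int(mask.sum())} "
      f"({mask.mean():.1%} of the slice)")
print(f"intensity range: [{first.image.values.min():.3f}, "
      f"{first.image.values.max():.3f}]  (normalised to [-1, 1])")

# the published label-fraction scenarios on 30 training cases
for fraction in (0.1, 0.2, 0.5, 0.8, 1.0):
    split = split_dataset(records, fraction, validation_split=0.0, seed=1)
    print(f"label fraction {fraction:4.0%}: {len(split.labeled):2d} labeled, "
          f"{len(split.pseudo_unlabeled)} pseudo-unlabeled")
# The pseudo-unlabeled pool always holds every training image with its
# label withheld: it feeds the unsupervised reconstruction branch.
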