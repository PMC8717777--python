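# Methods

## Problem setting

Delineating the ischemic penumbra — hypoperfused but salvageable tissue
around an infarct core — on multi-modal MRI is labour-intensive, and
labeled stroke datasets are small (a few dozen cases). The co-optimization
strategy implemented here leverages the unlabeled state of every training
image: an unsupervised reconstruction branch learns features from all
images, and a transfer block injects its bottleneck representation into the
supervised segmentation branch, so the segmenter benefits from images whose
labels it never sees. Every labeled sample also has a pseudo-unlabeled
state: the pseudo-unlabeled pool always contains *all* training images with
labels withheld, including those whose labels feed the segmenter.

## Networks

All four graphs are 2-D and operate on `(channel, row, column)` float32
slices normalised to [-1, 1].

* **Shared encoder layout** (R and S, independently initialized): a 3×3
  stem convolution to `base_width` channels, then `n_stages` (default 4)
  stages of two residual blocks each. The first block of a stage has
  stride 2 and doubles the channels, so the bottleneck holds
  `8·base_width` channels at H/16 × W/16. A residual block is a
  1×1 → 3×3 → 1×1 convolution path (each Conv-BN, ReLU after the first
  two) fused with the identity path; the default fusion is concatenation
  followed by a 1×1 projection back to the declared output width, with an
  elementwise-`add` option. The concat default is unusual for residual
  networks but is retained as the documented block design; `add` gives the
  classical residual behaviour and is exercised by the tests.
* **R (reconstructor)**: encoder + `n_stages` decoder stages of
  (nearest-neighbour ×2 upsample → Conv-BN-ReLU), a 1×1 head and Tanh.
  The Tanh output is clipped to ±(1 − 1e-6) so the documented open-interval
  range (−1, 1) holds even where float32 rounds tanh to exactly ±1 (the
  gradient there is ~0 regardless). The "middle" feature exposed to the
  transfer block is the deepest encoder output — the only feature whose
  shape matches S's bottleneck for additive fusion.
* **S (segmenter)**: encoder + U-style decoder — per stage: upsample ×2,
  concatenate the matching encoder feature, two Conv-BN-ReLU, dropout —
  then a 1×1 head and per-pixel softmax over 2 classes.
* **D (discriminator)**: four stride-2 3×3 convolutions with ReLU, a
  512-unit fully connected layer, a 2-unit layer and softmax; the output
  pair is read as (P(reconstructed), P(real)).
* **T (transfer block)**: Conv1×1 → BatchNorm → ReLU on R's middle
  feature, added elementwise onto S's bottleneck. With zeroed weights T is
  an exact additive identity, which the tests pin down.

Nearest-neighbour upsampling was chosen over transposed convolution for
determinism and the absence of checkerboard artifacts. BatchNorm uses
momentum 0.1 and running statistics in eval mode; with the default batch
of 3 the batch statistics are noisy, and batch size 1 is noticeably
unstable — avoid it. Dropout (rate 1e-2) sits after each decoder stage;
the rate is a published-schedule default, the placement is this package's
choice.

## Losses

* **Segmentation**: soft Dice, `1 − (2Σpt + s)/(Σp + Σt + s)` on
  foreground probabilities. During training `s = 1` (smooth; keeps empty
  masks finite and gradients stable); for reporting `s = 0`. The
  empty-vs-empty case at `s = 0` returns 0 by convention (a perfect match)
  with a warning.
* **Reconstruction (adversarial autoencoder)**: the generator side is
  `MSE(R(x), x) + adv_weight · CE(D(R(x)), real)` with `adv_weight = 1`;
  the discriminator side is `CE(D(x), real) + CE(D(R(x)), fake)`.
  Probabilities are clamped to [1e-7, 1 − 1e-7] before the log, so a
  maximally confident mistake costs ≈ 16.1, large but finite.
* **Mixed objective**: `loss_mix = loss_s + λ·loss_r`, default λ = 0.2.
  λ scales the reconstruction term, so λ = 0 recovers exactly the
  supervised loss — the property the λ-sweep and the supervised baseline
  rely on.

## Training procedure

Two phases, independently seeded and fully deterministic under a fixed
seed in single-threaded execution (the only caveat is a multi-threaded
BLAS changing reduction orders; the test suite and benchmark run
single-threaded semantics in practice):

1. **Reconstruction pretraining** on the pseudo-unlabeled pool: per batch
   one discriminator Adam step, then one generator step. The checkpoint
   with the lowest epoch-mean generator loss is kept.
2. **Joint co-optimization**: per step a labeled batch and an
   (independently shuffled) pseudo-unlabeled batch are drawn. R runs on
   the unlabeled batch (giving `loss_r`); R's encoder also runs on the
   labeled batch, T transfers that middle feature into S's bottleneck, and
   S decodes. One Adam step updates S, T and R on `loss_mix`; a separate
   step updates D. With λ = 0, R, T and D are neither run nor updated —
   the λ = 0 run is bit-identical to a purely supervised trainer, which a
   test asserts. `--freeze-recon` keeps R fixed during the joint phase.

Validation Dice (threshold-free argmax prediction, eval mode) is monitored
each epoch; the best-epoch weights are restored at the end, ties broken by
the earlier epoch, and training stops early after `patience` epochs
without improvement. When the validation carve-out is empty, 1 − train
Dice loss is monitored instead.

Published-schedule defaults (`TrainConfig`): R — 300 epochs, lr 1e-5;
S — 80 epochs, lr 1e-4; batch 3; dropout 1e-2; validation split 0.2;
Adam with conventional moments; random weight initialization (He normal).

## Synthetic phantoms

Each case is a 6-channel 64×64 slice at 2 mm isotropic spacing (both
configurable): an elliptical "brain" on a −1 background; a filled-ellipse
infarct core (semi-axes drawn from 3–7 px) surrounded by a penumbra
annulus (ring width 2–5 px) placed uniformly inside the brain; the
penumbra annulus is the segmentation target. Channel profiles emulate the
modality ordering DWI/CBV/Tmax/CBF/T2/TTP: the core is darkest on the
DWI-like channel 0, the penumbra contrast is strongest on the Tmax-like
perfusion channel 2. Gaussian noise (sd 0.05) is added and intensities are
clipped to [-1, 1], matching the reconstructor's Tanh range. Generation is
bitwise-deterministic per (seed, case index).

The phantoms emulate the *structure* a stroke slice presents to the
method — region contrast across modalities, lesion-inside-brain geometry,
spacing in mm — and deliberately nothing else: no MR physics, bias fields,
partial-volume effects, registration error, anatomy, or irregular lesion
shapes. Passing phantom benchmarks therefore demonstrates that the
optimization, fusion and bookkeeping behave as specified, not that
clinical-grade accuracy would be reached on real stroke MRI.

Label-fraction splitting rounds half-up, reproducing the published
30-record scenarios exactly (10/20/50/80/100% → 3/6/15/24/30 labeled); the
validation carve-out uses the same rounding but always leaves at least one
labeled training sample.

## Evaluation metrics

Surface pixels are foreground pixels with a background pixel among their
8-neighbours; the image border counts as background (the common challenge-
evaluator convention — stated explicitly because "surface pixel" is
otherwise ambiguous). Hausdorff distance is the exact maximum (not HD95)
of directed nearest-surface distances; ASSD averages the two directed mean
distances. Both use exact Euclidean distance transforms, are scaled by the
pixel spacing, and are reported in mm per 2-D slice. Either mask empty
makes HD/ASSD undefined: such cases are flagged, excluded from the HD/ASSD
aggregates, and keep their Dice (1 if both empty, else 0). Aggregates are
mean ± sample sd (n−1).

## The desk-scale benchmark

The standard benchmark (`colnet.benchmark`) uses 200 training and 50 test
phantom slices, three seeds, 10 joint epochs, and a slim profile chosen as
the package's CPU-scale operating point: `base_width = 4`, Adam lr 1e-3
for both phases (the conventional Adam default, paired with the short
schedules; the published 1e-5/1e-4 rates belong to the 300/80-epoch
schedules), 3 reconstruction-pretraining epochs, batch 3. Reconstruction
pretraining depends only on the seed, so it is shared across label
fractions within a seed. Two claims are checked: co-optimized λ = 0.2 at
20% labels stays within 0.02 mean test Dice of the supervised λ = 0
reference, and median test Dice is non-decreasing over the
10/20/50/100% label fractions for a majority of adjacent pairs. The whole
benchmark runs in about 5–6 minutes on one CPU.

## Numerical choices

* float32 throughout training; float64 inputs are preserved end-to-end by
  the autodiff engine for high-precision identity checks.
* CE probability clamp 1e-7; BatchNorm eps 1e-5; Adam eps 1e-8.
* Convolutions via im2col + BLAS matmul with a dedicated pointwise (1×1)
  fast path; gradients verified against float64 numerical differentiation.
* Seeds: every stochastic component (phantom case geometry/noise, weight
  init per network, batch shuffling, dropout) draws from its own
  `SeedSequence`-derived stream, so runs are reproducible and components
  are independently perturbable.
* If no labeled batch is available in a phase, the supervised update is
  skipped rather than rescaled; training without any labeled records is an
  error (the supervised loss is undefined).

## Known limitations

* 2-D slices only; volumetric (3-D) networks and per-volume evaluation are
  out of scope (metrics are per-slice).
* The exact residual depth/width of the original design is under-specified
  in its source; the ResNet-18-style layout here is a declared choice, and
  `base_width` scales it.
* The fused bottleneck feeds only S's decoder, not back into R.
* Unlabeled *test* data never participates in any training phase.
* Adversarial training at these scales is kept stable mainly by the small
  learning rates and the MSE term; no spectral normalisation or other GAN
  stabilisers are implemented.
* CPU-only by design; wall-clock scales roughly with
  `base_width²·H·W·batch` per step.
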