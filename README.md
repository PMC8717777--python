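# colnet

Semi-supervised segmentation of ischemic-penumbra lesions on multi-modal
MRI slices by **co-optimization**: a supervised segmentation network is
assisted by an unsupervised reconstruction network through a transfer block
that fuses the two encoder bottlenecks.

The package is aimed at researchers studying stroke-lesion segmentation
under label scarcity: it ships the full training method, a seed-
deterministic synthetic stroke-phantom generator (so everything is testable
without any data download), the SPES-challenge evaluation triplet
(Dice, Hausdorff distance, ASSD, all spacing-aware), NIfTI/PNG/manifest I/O
and a small CLI.

## The model

Three networks and a fusion block cooperate:

* **R — reconstruction network.** A residual encoder (3×3 stem + four
  stages of two residual blocks, channel-doubling, so the bottleneck sits
  at H/16 × W/16) with a plain upsampling decoder and Tanh output. R is an
  adversarial autoencoder trained on *pseudo-unlabeled* samples — training
  images with their labels deliberately withheld — with

  `loss_r = MSE(R(x), x) + CE(D(R(x)), real)`

  where the discriminator **D** (four strided 3×3 convolutions, FC-512,
  FC-2, softmax) is trained to separate reconstructions from real slices.
* **S — segmentation network.** The same encoder layout (independently
  initialized) with a U-style decoder (nearest-neighbour upsampling, skip
  connections, two Conv-BN-ReLU per stage) and per-pixel softmax, trained
  with the soft Dice loss `loss_s = 1 − 2|X∩Y| / (|X|+|Y|)`.
* **T — transfer block.** Conv1×1 → BatchNorm → ReLU applied to R's
  bottleneck ("middle") feature, fused into S's bottleneck by elementwise
  addition each forward pass.

Training is two-phase: R (+D) pretrains on all pseudo-unlabeled slices;
then S, T and R are optimized jointly on the mixed objective

`loss_mix = loss_s + λ · loss_r`

with Adam. λ = 0 disables the reconstruction branch entirely and recovers
purely supervised training; λ = 0.2 is the default. The best checkpoint by
validation Dice is kept (early stopping).

Because the networks must run on plain CPUs with no deep-learning
framework, they are built on `colnet.nn`, a compact NumPy reverse-mode
autodiff engine (im2col convolutions, batch norm, Adam) that is itself
fully gradient-tested against numerical differentiation.

## Worked example

`examples/03_train_cooptimized.py` trains on 60 phantom slices with 80%
labels and a short desk-scale schedule (~1 minute on one CPU):

```
38 labeled / 10 validation / 60 pseudo-unlabeled slices
reconstruction pretraining: MSE 0.5920 -> 0.4659
joint training: best epoch 3, validation DC 0.508
held-out test: DC 0.472 (+/- 0.085), HD 65.45 mm, ASSD 8.53 mm
```

The pretraining line shows the autoencoder's reconstruction error falling;
the final line scores the selected checkpoint on 10 held-out phantoms —
Dice overlap, then worst-case and average boundary error in millimetres at
the phantoms' 2 mm pixel spacing. Scores rise sharply with more data and
longer schedules: on the standard benchmark below (200 training slices)
the same configuration reaches mean test Dice ≈ 0.7 at 20% labels and
≈ 0.99 with all labels. The other examples demonstrate phantom generation
and the label-fraction scenarios (`01`), the metric triplet (`02`), the
label-fraction ablation (`04`) and the λ sweep (`05`).

A CLI mirrors the library:

```bash
colnet simulate --n-cases 30 --seed 7 --out data/
colnet train --manifest data/manifest.json --fraction 0.8 --lam 0.2 --out runs/r1
colnet predict --run runs/r1 --manifest data/manifest.json --out preds/
colnet evaluate --pred preds/ --truth data/manifest.json --out metrics.csv
```

## Layout

```
src/colnet/
  nn/          NumPy autodiff engine (tensor, layers, Adam)
  phantom.py   synthetic stroke-phantom generator + dataset splitting
  image_io.py  NIfTI/PNG volumes, masks, JSON manifests
  networks.py  R, S, D, T and the checkpointable model bundle
  losses.py    soft Dice, adversarial reconstruction loss, mixed loss
  metrics.py   Dice / Hausdorff / ASSD with surface extraction
  training.py  two-phase co-optimization + experiment runners
  benchmark.py the standard desk-scale phantom benchmark
  cli.py       thin click CLI over the library
docs/methods.md   model, parameter and design documentation
examples/         one short narrative script per capability
```

See `docs/methods.md` for assumptions, parameter defaults, what the
phantom generator does and does not emulate, and known limitations.
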