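"""Two-phase co-optimized training on a small phantom dataset.

Phase 1 pretrains the adversarial reconstruction branch R (+discriminator)
on all pseudo-unlabeled slices; phase 2 jointly optimizes the segmenter S,
the transfer block T and R on loss_mix = loss_s + lambda * loss_r, fusing
R's bottleneck feature into S's bottleneck each step. A short schedule on
60 slices keeps this demo around a minute.
"""

import numpy as np

from colnet import (PhantomConfig, generate_dataset, split_dataset, predict,
                    evaluate_cases, pretrain_reconstruction,
                    train_cooptimized, desk_scale_config)

train_records = generate_dataset(PhantomConfig(n_cases=60, seed=11))
test_records = generate_dataset(PhantomConfig(n_cases=10, seed=97))

config = desk_scale_config(lam=0.2, seed=1)
split = split_dataset(train_records, label_fraction=0.8,
                      validation_split=config.validation_split,
                      seed=config.seed)
print(f"{len(split.labeled)} labeled / {len(split.validation)} validation / "
      f"{len(split.pseudo_unlabeled)} pseudo-unlabeled slices")

model, recon_history = pretrain_reconstruction(split.pseudo_unlabeled, config)
print(f"reconstruction pretraining: MSE "
      f"{recon_history.train[0].loss_mse:.4f} -> "
      f"{recon_history.train[-1].loss_mse:.4f}")

model, history = train_cooptimized(split, config, model)
print(f"joint training: best epoch {history.best_epoch}, "
      f"validation DC {history.best_metric:.3f}")

preds = predict(model, test_records)
truths = {r.case_id: r.mask.values for r in test_records}
_, summary = evaluate_cases(preds, truths, spacing_mm=2.0)
print(f"held-out test: DC {summary['dc_mean']:.3f} "
      f"(+/- {summary['dc_sd']:.3f}), "
      f"HD {summary['hd_mean_mm']:.2f} mm, "
      f"ASSD {summary['assd_mean_mm']:.2f} mm")
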