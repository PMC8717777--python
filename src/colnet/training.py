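"""Two-phase co-optimization training and the experiment runners.

Phase 1 pretrains the reconstruction branch (R + discriminator D) on all
pseudo-unlabeled slices. Phase 2 trains jointly: each step draws a labeled
batch and a pseudo-unlabeled batch, computes the reconstruction loss on the
unlabeled batch, fuses R's bottleneck feature (computed on the labeled
batch) into S's bottleneck through the transfer block, and updates S, T
and R on ``loss_mix = loss_s + λ·loss_r`` while D is updated on its own
real-vs-fake loss. λ = 0 disables the reconstruction branch entirely, so a
λ = 0 run is bit-identical to a purely supervised trainer.

The best checkpoint is the epoch with maximal validation Dice (ties broken
by the earlier epoch); early stopping halts after ``patience`` epochs
without improvement.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .image_io import LabelMask
from .losses import (LossBreakdown, LossWeights, mix_loss,
                     reconstruction_loss, soft_dice_loss)
from .metrics import dice_coefficient, evaluate_cases
from .networks import (ColNetModel, NetworkConfig, as_batch, build_model,
                       transfer_fuse)
from .nn import Adam, Tensor
from .phantom import DatasetSplit, SampleRecord, split_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "PhaseConfig", "TrainConfig", "RunHistory", "desk_scale_config",
    "pretrain_reconstruction", "train_cooptimized", "predict",
    "run_label_fraction_experiment", "run_lambda_sweep",
]

_TRAIN_SMOOTH = 1.0     # Dice smoothing during training (stability on empties)


@dataclass(frozen=True)
class PhaseConfig:
    epochs: int
    lr: float
    batch: int = 3
    dropout: float = 0.01

    def __post_init__(self):
        if self.epochs < 0 or self.lr <= 0 or self.batch < 1:
            raise ValueError("epochs must be >= 0, lr > 0, batch >= 1")


@dataclass(frozen=True)
class TrainConfig:
    """Defaults follow the published schedule (R: 300 epochs at 1e-5,
    S: 80 epochs at 1e-4, batch 3, dropout 1e-2, validation split 0.2,
    λ = 0.2, Adam with conventional moments)."""

    recon: PhaseConfig = PhaseConfig(epochs=300, lr=1e-5)
    seg: PhaseConfig = PhaseConfig(epochs=80, lr=1e-4)
    validation_split: float = 0.2
    lam: float = 0.2
    adv_weight: float = 1.0
    seed: int = 0
    patience: int = 20
    freeze_recon: bool = False
    network: NetworkConfig = NetworkConfig()

    def __post_init__(self):
        if not 0.0 <= self.validation_split < 1.0:
            raise ValueError("validation_split must lie in [0, 1)")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")

    @property
    def weights(self) -> LossWeights:
        return LossWeights(lam=self.lam, adv_weight=self.adv_weight)


def desk_scale_config(lam: float = 0.2, seed: int = 0,
                      base_width: int = 4) -> TrainConfig:
    """The desk-scale profile used by the phantom benchmark: a slim network
    (base_width 4) and short schedules (3 reconstruction epochs, 10 joint
    epochs) with the conventional Adam rate 1e-3 for both phases."""
    return TrainConfig(
        recon=PhaseConfig(epochs=3, lr=1e-3),
        seg=PhaseConfig(epochs=10, lr=1e-3),
        lam=lam, seed=seed,
        patience=10,
        network=NetworkConfig(in_channels=6, base_width=base_width),
    )


@dataclass
class RunHistory:
    train: list[LossBreakdown] = field(default_factory=list)
    validation: list[LossBreakdown] = field(default_factory=list)
    val_dc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_metric: float = float("nan")

    def to_csv(self, path) -> None:
        rows = []
        for i, tb in enumerate(self.train):
            row = {"epoch": i, "split": "train", **asdict(tb)}
            rows.append(row)
            if i < len(self.validation):
                vb = asdict(self.validation[i])
                vb.update(epoch=i, split="validation",
                          val_dc=self.val_dc[i] if i < len(self.val_dc) else None)
                rows.append(vb)
        pd.DataFrame(rows).to_csv(path, index=False)


def _batches(n: int, batch: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch):
        yield order[i:i + batch]


def _stack_images(records: Sequence[SampleRecord], idx) -> Tensor:
    return as_batch([records[i].image for i in idx])


def _stack_masks(records: Sequence[SampleRecord], idx) -> np.ndarray:
    return np.stack([records[i].mask.values for i in idx]).astype(np.float32)


def _recon_step(model: ColNetModel, x: Tensor, opt_r: Adam, opt_d: Adam,
                weights: LossWeights) -> tuple[float, float, float]:
    """One D update then one R update on a batch; returns (mse, gen, disc)."""
    # discriminator step: real vs detached reconstruction
    recon, _ = model.r(x)
    d_real = model.d(x)
    d_fake = model.d(recon.detach())
    _, loss_d = reconstruction_loss(x, recon.detach(), d_fake, d_real, weights)
    opt_d.zero_grad()
    model.d.zero_grad()
    loss_d.backward()
    opt_d.step()
    # generator step: MSE + fool the just-updated discriminator; the forward
    # graph of `recon` is reused (R's weights have not changed since)
    d_fake = model.d(recon)
    mse = (recon - x).square().mean()
    loss_g, _ = reconstruction_loss(x, recon, d_fake, model.d(x).detach(), weights)
    opt_r.zero_grad()
    model.r.zero_grad()
    model.d.zero_grad()      # gradient flowed through D; discard it
    loss_g.backward()
    opt_r.step()
    return float(mse.data), float(loss_g.data), float(loss_d.data)


def pretrain_reconstruction(pseudo_records: Sequence[SampleRecord],
                            config: TrainConfig,
                            model: Optional[ColNetModel] = None
                            ) -> tuple[ColNetModel, RunHistory]:
    """Unsupervised phase: alternate D and R Adam steps on pseudo-unlabeled
    slices; returns the lowest-generator-loss checkpoint."""
    if not pseudo_records:
        raise ValueError("need at least one pseudo-unlabeled record")
    hw = pseudo_records[0].image.shape
    if model is None:
        model = build_model(config.network, config.seed, input_hw=hw)
    batch = config.recon.batch
    if batch > len(pseudo_records):
        logger.warning("batch %d larger than dataset %d; reducing",
                       batch, len(pseudo_records))
        batch = len(pseudo_records)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, 101]))
    opt_r = Adam(model.r.parameters(), lr=config.recon.lr)
    opt_d = Adam(model.d.parameters(), lr=config.recon.lr)
    history = RunHistory()
    best_loss, best_state = math.inf, None
    model.train()
    for epoch in range(config.recon.epochs):
        mses, gens, discs = [], [], []
        for idx in _batches(len(pseudo_records), batch, rng):
            x = _stack_images(pseudo_records, idx)
            mse, gen, disc = _recon_step(model, x, opt_r, opt_d, config.weights)
            mses.append(mse)
            gens.append(gen)
            discs.append(disc)
            model.step += 1
        breakdown = LossBreakdown(loss_mse=float(np.mean(mses)),
                                  loss_adv_g=float(np.mean(gens) - np.mean(mses)),
                                  loss_r=float(np.mean(gens)),
                                  loss_d=float(np.mean(discs)))
        history.train.append(breakdown)
        if breakdown.loss_r < best_loss:
            best_loss = breakdown.loss_r
            best_state = model.state_dict()
            history.best_epoch = epoch
            history.best_metric = best_loss
        logger.info("recon epoch %d: mse %.4f gen %.4f disc %.4f",
                    epoch, breakdown.loss_mse, breakdown.loss_r, breakdown.loss_d)
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def _validation_dice(model: ColNetModel, records: Sequence[SampleRecord],
                     batch: int) -> float:
    if not records:
        return float("nan")
    model.eval()
    dcs = []
    for i in range(0, len(records), batch):
        chunk = records[i:i + batch]
        probs = model.s(as_batch([r.image for r in chunk]))
        pred = (np.argmax(probs.data, axis=1) == 1).astype(np.uint8)
        for j, rec in enumerate(chunk):
            dcs.append(dice_coefficient(pred[j], rec.mask.values))
    model.train()
    return float(np.mean(dcs))


def _validation_losses(model: ColNetModel, records: Sequence[SampleRecord],
                       config: TrainConfig) -> LossBreakdown:
    """Eval-mode loss_s / loss_r / loss_mix on the validation records."""
    if not records:
        return LossBreakdown()
    model.eval()
    x = as_batch([r.image for r in records])
    masks = np.stack([r.mask.values for r in records]).astype(np.float32)
    loss_s = float(soft_dice_loss(
        model.s(x).data[:, 1], masks, smooth=_TRAIN_SMOOTH).data)
    if config.lam > 0:
        recon, _ = model.r(x)
        d_fake = model.d(recon)
        d_real = model.d(x)
        gen, disc = reconstruction_loss(x, recon, d_fake, d_real, config.weights)
        mse = float((recon - x).square().mean().data)
        loss_r, loss_d = float(gen.data), float(disc.data)
    else:
        mse = loss_d = float("nan")
        loss_r = 0.0
    loss_mix_val = loss_s + config.lam * loss_r
    model.train()
    return LossBreakdown(loss_s=loss_s, loss_r=loss_r, loss_mse=mse,
                         loss_d=loss_d, loss_mix=loss_mix_val)


def train_cooptimized(split: DatasetSplit, config: TrainConfig,
                      model: Optional[ColNetModel] = None
                      ) -> tuple[ColNetModel, RunHistory]:
    """Joint phase: optimize S (+T, +R when λ > 0) on the mixed loss.

    ``model`` normally arrives from :func:`pretrain_reconstruction`; a fresh
    model is built when it is omitted (or when λ = 0, where R is unused).
    """
    if not split.labeled:
        raise ValueError("no labeled records: supervised loss undefined "
                         "(λ=0 is meaningless without labels)")
    if config.lam > 0 and not split.pseudo_unlabeled:
        raise ValueError("λ > 0 requires pseudo-unlabeled records")
    hw = split.labeled[0].image.shape
    if model is None:
        model = build_model(config.network, config.seed, input_hw=hw)
    batch = min(config.seg.batch, len(split.labeled))
    if batch < config.seg.batch:
        logger.warning("batch %d larger than labeled set %d; reducing",
                       config.seg.batch, len(split.labeled))
    semi = config.lam > 0
    params = list(model.s.parameters())
    if semi:
        params += list(model.t.parameters())
        if not config.freeze_recon:
            params += list(model.r.parameters())
    opt = Adam(params, lr=config.seg.lr)
    opt_d = Adam(model.d.parameters(), lr=config.seg.lr) if semi else None
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, 202]))
    history = RunHistory()
    best_dc, best_epoch, best_state = -math.inf, -1, None
    n_lab = len(split.labeled)
    n_unlab = len(split.pseudo_unlabeled)
    model.train()
    for epoch in range(config.seg.epochs):
        unlab_order = rng.permutation(n_unlab) if semi else None
        stats = {"loss_s": [], "loss_r": [], "loss_mix": [],
                 "loss_mse": [], "loss_d": []}
        for step_i, idx in enumerate(_batches(n_lab, batch, rng)):
            x_lab = _stack_images(split.labeled, idx)
            y_lab = _stack_masks(split.labeled, idx)
            if semi:
                take = [unlab_order[(step_i * batch + k) % n_unlab]
                        for k in range(len(idx))]
                x_unlab = _stack_images(split.pseudo_unlabeled, take)
                # reconstruction side on the unlabeled batch
                recon, _ = model.r(x_unlab)
                d_fake = model.d(recon)
                mse = (recon - x_unlab).square().mean()
                loss_r, _ = reconstruction_loss(
                    x_unlab, recon, d_fake, model.d(x_unlab).detach(),
                    config.weights)
                # segmentation side with fused bottleneck on the labeled batch
                middle = model.r.encode(x_lab)
                skips, bneck = model.s.encode(x_lab)
                fused = transfer_fuse(middle, bneck, model.t)
                probs = model.s.decode(fused, skips)
                loss_s = soft_dice_loss(probs[:, 1], y_lab,
                                        smooth=_TRAIN_SMOOTH)
                loss = mix_loss(loss_s, loss_r, config.weights)
                opt.zero_grad()
                for net in (model.r, model.s, model.t, model.d):
                    net.zero_grad()
                loss.backward()
                opt.step()
                # discriminator update on its own loss; reuses the (slightly
                # stale) reconstruction from before the R update
                recon_d = recon.detach()
                d_fake2 = model.d(recon_d)
                d_real2 = model.d(x_unlab)
                _, loss_d = reconstruction_loss(
                    x_unlab, recon_d, d_fake2, d_real2, config.weights)
                opt_d.zero_grad()
                model.d.zero_grad()
                loss_d.backward()
                opt_d.step()
                stats["loss_r"].append(float(loss_r.data))
                stats["loss_mse"].append(float(mse.data))
                stats["loss_d"].append(float(loss_d.data))
            else:
                probs = model.s(x_lab)
                loss_s = soft_dice_loss(probs[:, 1], y_lab, smooth=_TRAIN_SMOOTH)
                loss = loss_s
                opt.zero_grad()
                model.s.zero_grad()
                loss.backward()
                opt.step()
            stats["loss_s"].append(float(loss_s.data))
            stats["loss_mix"].append(float(loss.data))
            model.step += 1
        train_bd = LossBreakdown(
            loss_s=float(np.mean(stats["loss_s"])),
            loss_r=float(np.mean(stats["loss_r"])) if stats["loss_r"] else 0.0,
            loss_mse=float(np.mean(stats["loss_mse"])) if stats["loss_mse"] else float("nan"),
            loss_d=float(np.mean(stats["loss_d"])) if stats["loss_d"] else float("nan"),
            loss_mix=float(np.mean(stats["loss_mix"])))
        history.train.append(train_bd)
        history.validation.append(
            _validation_losses(model, split.validation, config))
        vdc = _validation_dice(model, split.validation, batch)
        if math.isnan(vdc):      # no validation records: monitor training Dice
            vdc = 1.0 - train_bd.loss_s
        history.val_dc.append(vdc)
        logger.info("joint epoch %d: loss_s %.4f loss_r %.4f loss_mix %.4f "
                    "val_dc %.4f", epoch, train_bd.loss_s, train_bd.loss_r,
                    train_bd.loss_mix, vdc)
        if vdc > best_dc:        # strict >: ties keep the earlier epoch
            best_dc, best_epoch = vdc, epoch
            best_state = model.state_dict()
        elif epoch - best_epoch >= config.patience:
            logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    history.best_epoch = best_epoch
    history.best_metric = best_dc
    model.eval()
    return model, history


def predict(model: ColNetModel, records: Sequence[SampleRecord],
            batch: int = 8) -> dict[str, LabelMask]:
    """Argmax segmentation masks per case, deterministic in eval mode."""
    model.eval()
    out: dict[str, LabelMask] = {}
    for i in range(0, len(records), batch):
        chunk = records[i:i + batch]
        probs = model.s(as_batch([r.image for r in chunk]))
        pred = (np.argmax(probs.data, axis=1) == 1).astype(np.uint8)
        for j, rec in enumerate(chunk):
            out[rec.case_id] = LabelMask(pred[j], spacing_mm=rec.spacing_mm)
    return out


def _evaluate_on_test(model: ColNetModel, test_records: Sequence[SampleRecord],
                      spacing_mm: float):
    preds = predict(model, test_records)
    truths = {r.case_id: r.mask.values for r in test_records}
    return evaluate_cases(preds, truths, spacing_mm=spacing_mm)


def train_full(train_records: Sequence[SampleRecord], config: TrainConfig,
               label_fraction: float = 1.0,
               pretrained: Optional[ColNetModel] = None
               ) -> tuple[ColNetModel, RunHistory, DatasetSplit]:
    """Split, (pre)train and co-optimize in one call; returns the best model."""
    split = split_dataset(train_records, label_fraction,
                          validation_split=config.validation_split,
                          seed=config.seed)
    model = pretrained
    if config.lam > 0 and model is None:
        model, _ = pretrain_reconstruction(split.pseudo_unlabeled, config)
    model, history = train_cooptimized(split, config, model)
    return model, history, split


def run_label_fraction_experiment(
        train_records: Sequence[SampleRecord],
        test_records: Sequence[SampleRecord],
        config: TrainConfig,
        fractions: Sequence[float] = (0.1, 0.2, 0.5, 0.8, 1.0),
        seeds: Sequence[int] = (0,)) -> pd.DataFrame:
    """One co-optimized run per (fraction, seed); mean±sd DC/HD/ASSD on the
    held-out test phantoms, in the layout of a label-fraction ablation table.

    The reconstruction pretraining depends only on the seed (all training
    records are pseudo-unlabeled regardless of fraction), so it is shared
    across fractions within a seed.
    """
    spacing = test_records[0].spacing_mm if test_records else 1.0
    rows = []
    for seed in seeds:
        cfg_seed = _with(config, seed=int(seed))
        pretrained_state = None
        if config.lam > 0:
            split_all = split_dataset(train_records, 1.0,
                                      config.validation_split, seed=int(seed))
            pre_model, _ = pretrain_reconstruction(split_all.pseudo_unlabeled,
                                                   cfg_seed)
            pretrained_state = pre_model.state_dict()
        for frac in fractions:
            pre = None
            if pretrained_state is not None:
                pre = build_model(cfg_seed.network, cfg_seed.seed,
                                  input_hw=train_records[0].image.shape)
                pre.load_state_dict(pretrained_state)
            model, history, _ = train_full(train_records, cfg_seed,
                                           label_fraction=frac, pretrained=pre)
            _, summary = _evaluate_on_test(model, test_records, spacing)
            rows.append({"fraction": frac, "seed": seed,
                         "dc_mean": summary["dc_mean"], "dc_sd": summary["dc_sd"],
                         "assd_mean_mm": summary["assd_mean_mm"],
                         "assd_sd_mm": summary["assd_sd_mm"],
                         "hd_mean_mm": summary["hd_mean_mm"],
                         "hd_sd_mm": summary["hd_sd_mm"],
                         "best_epoch": history.best_epoch})
    return pd.DataFrame(rows)


def run_lambda_sweep(train_records: Sequence[SampleRecord],
                     config: TrainConfig,
                     lams: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
                     label_fraction: float = 0.8,
                     test_records: Sequence[SampleRecord] = ()
                     ) -> dict[float, dict]:
    """Train once per λ on identical data/seed; returns per-λ histories,
    final validation Dice, and test summaries when test records are given."""
    out: dict[float, dict] = {}
    pretrained_state = None
    for lam in lams:
        cfg = _with(config, lam=float(lam))
        pre = None
        if lam > 0:
            if pretrained_state is None:
                split_all = split_dataset(train_records, 1.0,
                                          config.validation_split,
                                          seed=config.seed)
                pre_model, _ = pretrain_reconstruction(
                    split_all.pseudo_unlabeled, cfg)
                pretrained_state = pre_model.state_dict()
            pre = build_model(cfg.network, cfg.seed,
                              input_hw=train_records[0].image.shape)
            pre.load_state_dict(pretrained_state)
        model, history, _ = train_full(train_records, cfg,
                                       label_fraction=label_fraction,
                                       pretrained=pre)
        entry = {"history": history,
                 "final_val_dc": history.best_metric}
        if test_records:
            _, entry["test_summary"] = _evaluate_on_test(
                model, test_records, test_records[0].spacing_mm)
        out[float(lam)] = entry
    return out


def _with(config: TrainConfig, **kw) -> TrainConfig:
    d = {f: getattr(config, f) for f in config.__dataclass_fields__}
    d.update(kw)
    return TrainConfig(**d)
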