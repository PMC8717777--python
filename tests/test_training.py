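"""Training orchestration: determinism, checkpointing/early-stopping
bookkeeping, learning smoke tests and the experiment runners.

All tests use a tiny profile (16x16 or 32x32 slices, 2-stage encoders,
base width 4) so the whole module runs in well under a minute.
"""

import dataclasses

import numpy as np
import pytest

from colnet.losses import LossWeights, mix_loss
from colnet.metrics import dice_coefficient
from colnet.networks import NetworkConfig, build_model
from colnet.phantom import PhantomConfig, generate_dataset, split_dataset
from colnet.training import (PhaseConfig, TrainConfig, predict,
                             pretrain_reconstruction,
                             run_label_fraction_experiment, run_lambda_sweep,
                             train_cooptimized, train_full)

TINY_NET = NetworkConfig(in_channels=3, base_width=4, n_stages=2)


def tiny_config(lam=0.2, seed=0, recon_epochs=2, seg_epochs=3) -> TrainConfig:
    return TrainConfig(recon=PhaseConfig(epochs=recon_epochs, lr=1e-3),
                       seg=PhaseConfig(epochs=seg_epochs, lr=1e-3),
                       lam=lam, seed=seed, patience=10, network=TINY_NET)


@pytest.fixture(scope="module")
def tiny_records():
    cfg = PhantomConfig(n_cases=12, height=32, width=32, n_channels=3,
                        core_radius_range=(2.0, 4.0),
                        ring_width_range=(1.5, 3.0), seed=7)
    return generate_dataset(cfg)


@pytest.fixture(scope="module")
def tiny_split(tiny_records):
    return split_dataset(tiny_records, 1.0, validation_split=0.2, seed=7)


def _history_vector(history):
    return [(b.loss_s, b.loss_r, b.loss_mix) for b in history.train]


class TestPretrainReconstruction:
    def test_zero_epochs_returns_initial_state(self, tiny_split):
        model, history = pretrain_reconstruction(
            tiny_split.pseudo_unlabeled, tiny_config(recon_epochs=0))
        assert history.train == []
        assert model.step == 0

    def test_fixed_seed_reruns_identical(self, tiny_split):
        _, h1 = pretrain_reconstruction(tiny_split.pseudo_unlabeled,
                                        tiny_config(seed=5))
        _, h2 = pretrain_reconstruction(tiny_split.pseudo_unlabeled,
                                        tiny_config(seed=5))
        assert [(b.loss_mse, b.loss_r, b.loss_d) for b in h1.train] == \
            [(b.loss_mse, b.loss_r, b.loss_d) for b in h2.train]

    def test_batch_reduced_with_warning(self, tiny_split, caplog):
        cfg = dataclasses.replace(tiny_config(recon_epochs=1),
                                  recon=PhaseConfig(epochs=1, lr=1e-3, batch=99))
        with caplog.at_level("WARNING"):
            pretrain_reconstruction(tiny_split.pseudo_unlabeled, cfg)
        assert any("reducing" in r.message for r in caplog.records)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mse_decreases_over_training(self, seed):
        """Learning smoke test: 10 slices, 8 epochs, final MSE < initial."""
        cfg = PhantomConfig(n_cases=10, height=32, width=32, n_channels=3,
                            core_radius_range=(2.0, 4.0),
                            ring_width_range=(1.5, 3.0), seed=100 + seed)
        split = split_dataset(generate_dataset(cfg), 1.0, 0.0, seed=seed)
        _, history = pretrain_reconstruction(
            split.pseudo_unlabeled, tiny_config(seed=seed, recon_epochs=8))
        assert history.train[-1].loss_mse < history.train[0].loss_mse


class TestTrainCooptimized:
    def test_requires_labeled_records(self, tiny_split):
        empty = dataclasses.replace(tiny_split, labeled=[])
        with pytest.raises(ValueError, match="labeled"):
            train_cooptimized(empty, tiny_config())

    def test_lambda_zero_leaves_r_t_d_untouched(self, tiny_split):
        cfg = tiny_config(lam=0.0, seg_epochs=2)
        model = build_model(cfg.network, cfg.seed, input_hw=(32, 32))
        before = {k: v.copy() for k, v in model.state_dict().items()
                  if k.startswith(("r.", "t.", "d."))}
        trained, _ = train_cooptimized(tiny_split, cfg, model)
        after = trained.state_dict()
        for k, v in before.items():
            np.testing.assert_array_equal(after[k], v)

    def test_lambda_zero_runs_are_bit_identical(self, tiny_split):
        cfg = tiny_config(lam=0.0, seg_epochs=2, seed=3)
        m1, h1 = train_cooptimized(tiny_split, cfg)
        m2, h2 = train_cooptimized(tiny_split, cfg)
        assert _history_vector(h1) == _history_vector(h2)
        s1, s2 = m1.state_dict(), m2.state_dict()
        for k in s1:
            np.testing.assert_array_equal(s1[k], s2[k])

    def test_joint_fixed_seed_reruns_identical(self, tiny_split):
        cfg = tiny_config(seed=4, seg_epochs=2)
        pre1, _ = pretrain_reconstruction(tiny_split.pseudo_unlabeled, cfg)
        _, h1 = train_cooptimized(tiny_split, cfg, pre1)
        pre2, _ = pretrain_reconstruction(tiny_split.pseudo_unlabeled, cfg)
        _, h2 = train_cooptimized(tiny_split, cfg, pre2)
        assert _history_vector(h1) == _history_vector(h2)
        assert h1.val_dc == h2.val_dc

    def test_best_checkpoint_is_argmax_validation_dc(self, tiny_split):
        cfg = tiny_config(seed=5, seg_epochs=4)
        model, history = train_cooptimized(tiny_split, cfg)
        assert history.best_epoch == int(np.argmax(history.val_dc))
        assert history.best_metric == max(history.val_dc)
        assert history.best_metric >= history.val_dc[0]

    def test_returned_model_reproduces_best_validation_dice(self, tiny_split):
        cfg = tiny_config(lam=0.0, seed=6, seg_epochs=3)
        model, history = train_cooptimized(tiny_split, cfg)
        preds = predict(model, tiny_split.validation)
        dcs = [dice_coefficient(preds[r.case_id].values, r.mask.values)
               for r in tiny_split.validation]
        assert np.mean(dcs) == pytest.approx(history.best_metric, abs=1e-6)

    def test_early_stopping_respects_patience(self, tiny_split):
        cfg = dataclasses.replace(tiny_config(lam=0.0, seg_epochs=30, seed=8),
                                  patience=2)
        _, history = train_cooptimized(tiny_split, cfg)
        n = len(history.val_dc)
        assert n <= 30
        if n < 30:   # stopped early: no improvement in the last `patience`
            assert history.best_epoch <= n - 1 - cfg.patience


class TestPredict:
    def test_deterministic_and_binary(self, tiny_split):
        cfg = tiny_config(lam=0.0, seg_epochs=1)
        model, _ = train_cooptimized(tiny_split, cfg)
        p1 = predict(model, tiny_split.validation)
        p2 = predict(model, tiny_split.validation)
        for cid in p1:
            assert p1[cid].values.shape == (32, 32)
            assert set(np.unique(p1[cid].values)) <= {0, 1}
            np.testing.assert_array_equal(p1[cid].values, p2[cid].values)


class TestCheckpointRoundTrip:
    def test_forward_outputs_identical_after_reload(self, tmp_path, tiny_split):
        from colnet.networks import ColNetModel, as_batch
        cfg = tiny_config(seed=9, seg_epochs=1)
        model, _ = train_cooptimized(tiny_split, cfg)
        x = as_batch([tiny_split.labeled[0].image])
        before = model.s(x).data.copy()
        model.save(tmp_path / "ckpt.npz")
        loaded = ColNetModel.load(tmp_path / "ckpt.npz").eval()
        np.testing.assert_array_equal(loaded.s(x).data, before)


class TestExperimentRunners:
    def test_fraction_experiment_row_count(self, tiny_records):
        test_recs = generate_dataset(
            PhantomConfig(n_cases=4, height=32, width=32, n_channels=3,
                          core_radius_range=(2.0, 4.0),
                          ring_width_range=(1.5, 3.0), seed=900))
        cfg = tiny_config(seg_epochs=1, recon_epochs=1)
        table = run_label_fraction_experiment(
            tiny_records, test_recs, cfg, fractions=[0.5, 1.0], seeds=[0])
        assert len(table) == 2
        assert set(table["fraction"]) == {0.5, 1.0}

    def test_fraction_experiment_single_row(self, tiny_records):
        test_recs = generate_dataset(
            PhantomConfig(n_cases=3, height=32, width=32, n_channels=3,
                          core_radius_range=(2.0, 4.0),
                          ring_width_range=(1.5, 3.0), seed=901))
        cfg = tiny_config(lam=0.0, seg_epochs=1)
        table = run_label_fraction_experiment(
            tiny_records, test_recs, cfg, fractions=[1.0], seeds=[0])
        assert len(table) == 1

    def test_lambda_sweep_returns_history_per_lambda(self, tiny_records):
        cfg = tiny_config(seg_epochs=2, recon_epochs=1)
        grid = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
        out = run_lambda_sweep(tiny_records, cfg, lams=grid,
                               label_fraction=1.0)
        assert set(out) == set(grid)
        for entry in out.values():
            assert len(entry["history"].train) == 2

    def test_lambda_zero_sweep_equals_supervised_curve(self, tiny_records):
        cfg = tiny_config(seg_epochs=2, recon_epochs=1)
        out = run_lambda_sweep(tiny_records, cfg, lams=(0.0,),
                               label_fraction=1.0)
        hist = out[0.0]["history"]
        for b in hist.train:
            assert b.loss_mix == b.loss_s
        sup, sup_hist, _ = train_full(
            tiny_records, dataclasses.replace(cfg, lam=0.0), 1.0)
        assert _history_vector(sup_hist) == _history_vector(hist)

    def test_mix_loss_nondecreasing_in_lambda_at_fixed_losses(self, rng):
        """Evaluated (not trained) property: for loss_r > 0 the mixed loss
        grows with lambda."""
        for _ in range(100):
            s = float(rng.random())
            r = float(rng.random()) + 1e-3
            vals = [mix_loss(s, r, LossWeights(lam=l))
                    for l in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)]
            assert all(v2 >= v1 for v1, v2 in zip(vals, vals[1:]))
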