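"""Shape-and-range contracts of the four computation graphs and the
additive bottleneck fusion."""

import numpy as np
import pytest

from colnet.networks import (ColNetModel, DiscriminatorNet, NetworkConfig,
                             ResidualBlock, SegmenterNet, TransferBlock,
                             build_model, forward_discriminator,
                             forward_reconstructor, forward_segmenter,
                             transfer_fuse)
from colnet.nn import Adam, Tensor

CFG = NetworkConfig(in_channels=6, base_width=4)
SMALL = NetworkConfig(in_channels=2, base_width=4, n_stages=2)


def _zero_block(block: ResidualBlock) -> None:
    for conv in (block.conv1, block.conv2, block.conv3):
        conv.weight.data[...] = 0
        conv.bias.data[...] = 0


class TestResidualBlock:
    def test_shape_contract_stride1(self, rng):
        block = ResidualBlock(16, 16, rng, stride=1)
        out = block(Tensor(rng.standard_normal((1, 16, 32, 32)).astype(np.float32)))
        assert out.shape == (1, 16, 32, 32)

    def test_shape_contract_stride2(self, rng):
        block = ResidualBlock(8, 16, rng, stride=2)
        out = block(Tensor(rng.standard_normal((2, 8, 32, 32)).astype(np.float32)))
        assert out.shape == (2, 16, 16, 16)

    def test_zero_weights_add_fusion_is_identity(self, rng):
        block = ResidualBlock(8, 8, rng, stride=1, fusion="add")
        _zero_block(block)
        block.eval()
        x = Tensor(rng.standard_normal((1, 8, 16, 16)).astype(np.float32))
        np.testing.assert_array_equal(block(x).data, x.data)

    def test_channel_mismatch_raises(self, rng):
        block = ResidualBlock(8, 8, rng)
        with pytest.raises(ValueError, match="channel"):
            block(Tensor(np.zeros((1, 4, 16, 16), np.float32)))


class TestSegmenter:
    def test_softmax_output_valid_distribution(self, rng):
        model = build_model(CFG, seed=0)
        x = rng.standard_normal((1, 6, 64, 64)).astype(np.float32)
        probs = forward_segmenter(model.eval(), [x[0]]).data
        assert probs.shape == (1, 2, 64, 64)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert (probs >= 0).all()

    def test_batch_order_preserved(self, rng):
        model = build_model(CFG, seed=0).eval()
        xs = [rng.standard_normal((6, 64, 64)).astype(np.float32)
              for _ in range(3)]
        batched = forward_segmenter(model, xs).data
        singles = [forward_segmenter(model, [x]).data[0] for x in xs]
        for i in range(3):
            np.testing.assert_allclose(batched[i], singles[i], atol=1e-5)

    def test_indivisible_dims_hint_pad(self, rng):
        model = build_model(CFG, seed=0)
        with pytest.raises(ValueError, match="pad"):
            forward_segmenter(model, [np.zeros((6, 60, 60), np.float32)])

    @pytest.mark.parametrize("trial", range(10))
    def test_distribution_property_random_weights(self, trial):
        rng = np.random.default_rng(trial)
        model = build_model(SMALL, seed=trial, input_hw=(16, 16)).eval()
        x = rng.standard_normal((2, 2, 16, 16)).astype(np.float32) * 3
        probs = model.s(Tensor(x)).data
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert (probs >= 0).all()


class TestReconstructor:
    def test_output_shape_and_tanh_range(self, rng):
        model = build_model(CFG, seed=1).eval()
        x = rng.standard_normal((2, 6, 64, 64)).astype(np.float32) * 5
        recon, middle = forward_reconstructor(model, Tensor(x))
        assert recon.shape == (2, 6, 64, 64)
        assert (recon.data > -1).all() and (recon.data < 1).all()
        assert middle.shape[2:] == (4, 4)       # 64 / 2^4

    def test_eval_mode_deterministic(self, rng):
        model = build_model(CFG, seed=1).eval()
        x = Tensor(rng.standard_normal((1, 6, 64, 64)).astype(np.float32))
        r1, _ = forward_reconstructor(model, x)
        r2, _ = forward_reconstructor(model, x)
        np.testing.assert_array_equal(r1.data, r2.data)

    def test_encoders_same_shapes_different_values(self):
        model = build_model(CFG, seed=2)
        r_state = model.r.encoder.state_dict()
        s_state = model.s.encoder.state_dict()
        assert set(r_state) == set(s_state)
        for k in r_state:
            assert r_state[k].shape == s_state[k].shape
        assert any(not np.array_equal(r_state[k], s_state[k])
                   for k in r_state if "weight" in k or "conv" in k)


class TestDiscriminator:
    def test_probability_pairs(self, rng):
        model = build_model(CFG, seed=3).eval()
        x = rng.standard_normal((3, 6, 64, 64)).astype(np.float32)
        pairs = forward_discriminator(model, Tensor(x)).data
        assert pairs.shape == (3, 2)
        np.testing.assert_allclose(pairs.sum(axis=1), 1.0, atol=1e-5)

    def test_learns_separable_toy_problem(self, rng):
        cfg = NetworkConfig(in_channels=1, base_width=8, n_stages=2)
        disc = DiscriminatorNet(cfg, rng, input_hw=(16, 16))
        opt = Adam(disc.parameters(), lr=3e-3)
        reals = rng.standard_normal((32, 1, 16, 16)).astype(np.float32) + 2.0
        fakes = rng.standard_normal((32, 1, 16, 16)).astype(np.float32) - 2.0
        from colnet.losses import cross_entropy_pair, LABEL_FAKE, LABEL_REAL
        for step in range(40):
            i = rng.integers(0, 32, size=8)
            loss = cross_entropy_pair(disc(Tensor(reals[i])), LABEL_REAL) + \
                cross_entropy_pair(disc(Tensor(fakes[i])), LABEL_FAKE)
            disc.zero_grad()
            loss.backward()
            opt.step()
        disc.eval()
        acc = np.mean(np.concatenate([
            disc(Tensor(reals)).data[:, 1] > 0.5,
            disc(Tensor(fakes)).data[:, 0] > 0.5]))
        assert acc > 0.9


class TestTransferFuse:
    def test_zeroed_t_is_additive_identity(self, rng):
        t = TransferBlock(SMALL, rng)
        t.conv.weight.data[...] = 0
        t.conv.bias.data[...] = 0
        t.eval()
        ch = SMALL.bottleneck_channels
        a = Tensor(rng.standard_normal((1, ch, 4, 4)).astype(np.float32))
        b = Tensor(rng.standard_normal((1, ch, 4, 4)).astype(np.float32))
        np.testing.assert_array_equal(transfer_fuse(a, b, t).data, b.data)

    def test_identity_t_adds_elementwise(self, rng):
        t = TransferBlock(SMALL, rng)
        ch = SMALL.bottleneck_channels
        t.conv.weight.data[...] = np.eye(ch, dtype=np.float32)[:, :, None, None]
        t.conv.bias.data[...] = 0
        t.eval()                       # BN with running stats (0, 1)
        a = Tensor(np.abs(rng.standard_normal((1, ch, 4, 4))).astype(np.float32))
        b = Tensor(rng.standard_normal((1, ch, 4, 4)).astype(np.float32))
        np.testing.assert_allclose(transfer_fuse(a, b, t).data,
                                   a.data + b.data, atol=1e-4)

    def test_spatial_mismatch_raises(self, rng):
        t = TransferBlock(SMALL, rng)
        ch = SMALL.bottleneck_channels
        a = Tensor(np.zeros((1, ch, 4, 4), np.float32))
        b = Tensor(np.zeros((1, ch, 8, 8), np.float32))
        with pytest.raises(ValueError, match="patial"):
            transfer_fuse(a, b, t)

    def test_convolution_distributes_over_addition(self, rng):
        """add() fusion commutes with convolution: conv(K, f1+f2) equals
        conv(K, f1) + conv(K, f2), checked against a brute-force conv."""
        f1 = rng.standard_normal((1, 3, 8, 8)).astype(np.float32)
        f2 = rng.standard_normal((1, 3, 8, 8)).astype(np.float32)
        k = rng.standard_normal((2, 3, 3, 3)).astype(np.float32)

        def brute_conv(x):
            out = np.zeros((1, 2, 6, 6), dtype=np.float64)
            for f in range(2):
                for c in range(3):
                    for i in range(6):
                        for j in range(6):
                            out[0, f, i, j] += np.sum(
                                x[0, c, i:i + 3, j:j + 3] * k[f, c])
            return out

        lhs = brute_conv(f1 + f2)
        rhs = brute_conv(f1) + brute_conv(f2)
        np.testing.assert_allclose(lhs, rhs, atol=1e-5)
        # and the engine's convolution agrees with the brute-force one
        eng = Tensor(f1 + f2).conv2d(Tensor(k)).data
        np.testing.assert_allclose(eng, lhs, atol=1e-4)


class TestCheckpoint:
    def test_save_load_reproduces_forward_exactly(self, tmp_path, rng):
        model = build_model(SMALL, seed=5, input_hw=(16, 16)).eval()
        x = Tensor(rng.standard_normal((2, 2, 16, 16)).astype(np.float32))
        before_s = model.s(x).data.copy()
        before_r, _ = model.r(x)
        path = tmp_path / "ckpt.npz"
        model.save(path)
        loaded = ColNetModel.load(path).eval()
        np.testing.assert_array_equal(loaded.s(x).data, before_s)
        rec, _ = loaded.r(x)
        np.testing.assert_array_equal(rec.data, before_r.data)

    def test_config_echo_round_trip(self, tmp_path):
        model = build_model(SMALL, seed=5, input_hw=(16, 16))
        model.step = 123
        path = tmp_path / "ckpt.npz"
        model.save(path)
        loaded = ColNetModel.load(path)
        assert loaded.config == SMALL
        assert loaded.step == 123
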