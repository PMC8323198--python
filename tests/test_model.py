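import numpy as np
import pytest

import msffnet as mf
from msffnet.losses import LOSS_REGISTRY
from msffnet.model import NetConfig
from msffnet.nn import Adam

from .oracles import naive_msffn_param_count


class TestConfig:
    def test_input_size_must_be_divisible_by_16(self):
        with pytest.raises(ValueError, match="divisible by 16"):
            NetConfig(input_size=100)

    def test_default_stage_layout(self):
        cfg = NetConfig()
        assert cfg.stage_units == (4, 2, 2, 2, 2)
        assert cfg.stage_channels == (16, 32, 64, 128, 256)


class TestFEN:
    def test_tap_resolutions_at_176(self):
        fen = mf.build_fen(NetConfig(input_size=176))
        assert fen.tap_resolutions == (176, 176, 176, 176, 88, 44, 22, 11)

    def test_tap_resolutions_at_64(self):
        fen = mf.build_fen(NetConfig(input_size=64))
        assert fen.tap_resolutions == (64, 64, 64, 64, 32, 16, 8, 4)

    def test_twelve_conv_layers(self):
        assert mf.build_fen(NetConfig()).num_conv_layers == 12

    def test_tap_shapes_match_contract(self, tiny_net_config, rng):
        model = mf.MSFFNet(tiny_net_config)
        x = rng.normal(size=(1, 16, 16, 4)).astype(np.float32)
        taps = model.fen.forward(x)
        assert len(taps) == 8
        for t, res, ch in zip(taps, model.fen.tap_resolutions, model.fen.tap_channels):
            assert t.shape == (1, res, res, ch)


class TestMSFFN:
    def test_default_concat_channel_count(self):
        model = mf.build_model(NetConfig())
        assert model.msffn.concat_channels == 4 * 16 + 32 + 64 + 128 + 256 == 544

    def test_three_fusing_units(self):
        model = mf.build_model(NetConfig())
        assert len(model.msffn.fuse_units) == 3

    def test_standalone_head_consumes_fen_taps(self, tiny_net_config, rng):
        fen = mf.build_fen(tiny_net_config)
        head = mf.build_msffn(tiny_net_config)
        taps = fen.forward(rng.normal(size=(1, 16, 16, 4)).astype(np.float32))
        P = head.forward(taps)
        assert P.shape == (1, 16, 16, 5)
        assert np.abs(P.sum(-1) - 1.0).max() < 1e-5

    def test_softmax_normalization(self, tiny_net_config, rng):
        model = mf.MSFFNet(tiny_net_config)
        P = model.forward(rng.normal(size=(2, 16, 16, 4)).astype(np.float32))
        assert np.abs(P.sum(-1) - 1.0).max() < 1e-5
        assert P.min() >= 0.0


class TestFullModel:
    def test_output_shape_contract(self, tiny_net_config, rng):
        model = mf.MSFFNet(tiny_net_config)
        P = model.forward(rng.normal(size=(2, 16, 16, 4)).astype(np.float32))
        assert P.shape == (2, 16, 16, 5)

    def test_eval_mode_deterministic(self, rng):
        cfg = NetConfig(input_size=16, stage_channels=(4, 6, 8, 10, 12),
                        fusing_channels=8, dropout_rate=0.3, seed=2)
        model = mf.MSFFNet(cfg)
        x = rng.normal(size=(1, 16, 16, 4)).astype(np.float32)
        a = model.forward(x, training=False)
        b = model.forward(x, training=False)
        np.testing.assert_array_equal(a, b)

    def test_wrong_channel_count_rejected(self, tiny_net_config, rng):
        model = mf.MSFFNet(tiny_net_config)
        with pytest.raises(ValueError, match="expected input"):
            model.forward(rng.normal(size=(1, 16, 16, 3)))

    def test_one_hl2_step_has_finite_gradients_and_decreases_loss(self, tiny_net_config, rng):
        model = mf.MSFFNet(tiny_net_config)
        x = rng.normal(size=(2, 16, 16, 4)).astype(np.float32)
        G = mf.one_hot(rng.integers(0, 5, (2, 16, 16)))
        loss_fn = LOSS_REGISTRY["hl2"]
        opt = Adam(model.params())
        P = model.forward(x, training=True)
        v0, dP = loss_fn(P, G, None)
        opt.zero_grad()
        model.backward(dP.astype(np.float32))
        assert all(np.isfinite(p.grad).all() for p in model.params())
        opt.step(1e-3)
        v1, _ = loss_fn(model.forward(x, training=True), G, None)
        assert v1 < v0

    def test_every_tap_influences_output(self, tiny_net_config, rng):
        """Zeroing any single tap must change the logits (no dead branch)."""
        model = mf.MSFFNet(tiny_net_config)
        x = rng.normal(size=(1, 16, 16, 4)).astype(np.float32)
        base = model.forward(x, training=False)
        for i in range(8):
            mask = [j != i for j in range(8)]
            ablated = model.forward(x, training=False, tap_mask=mask)
            assert np.abs(ablated - base).max() > 1e-7, f"tap {i} is dead"

    def test_translation_equivariance_with_wrap_padding(self, rng):
        """Shifting the input by 16 px (wrap) shifts the output identically.

        Uses circular padding end-to-end so the convolution/pool/upsample
        stack is exactly shift-equivariant for multiples of 16 (the total
        pooling factor)."""
        cfg = NetConfig(input_size=64, stage_channels=(4, 6, 8, 10, 12),
                        fusing_channels=8, dropout_rate=0.0,
                        padding_mode="circular", seed=4)
        model = mf.MSFFNet(cfg)
        x = rng.normal(size=(1, 64, 64, 4)).astype(np.float32)
        shift = 16
        x_shift = np.roll(x, shift, axis=1)
        P = model.forward(x, training=False)
        P_shift = model.forward(x_shift, training=False)
        np.testing.assert_allclose(np.roll(P, shift, axis=1), P_shift, atol=1e-4)

    def test_runs_at_any_multiple_of_16(self, rng):
        for size in (16, 32, 48):
            cfg = NetConfig(input_size=size, stage_channels=(3, 4, 5, 6, 7),
                            fusing_channels=6, seed=0)
            model = mf.MSFFNet(cfg)
            P = model.forward(rng.normal(size=(1, size, size, 4)).astype(np.float32))
            assert P.shape == (1, size, size, 5)


class TestParameterCount:
    def test_single_conv_unit_counts(self):
        from msffnet.nn import BatchNorm2d, Conv2d

        conv = Conv2d(4, 16, ksize=3)
        assert sum(p.data.size for p in conv.params()) == 4 * 16 * 9 + 16 == 592
        bn = BatchNorm2d(16)
        n = sum(p.data.size for p in bn.params()) + sum(a.size for a in bn.state())
        assert n == 64

    def test_default_model_prints_6_3_megabytes(self):
        """Default architecture: 6.3 MB of parameters at one decimal.

        Cross-checked against an independent layer-by-layer arithmetic sum of
        every kernel, bias and BN term."""
        oracle = naive_msffn_param_count()
        model = mf.build_model()
        count, nbytes = mf.count_parameters(model)
        assert count == oracle
        assert round(nbytes / 1e6, 1) == 6.3

    def test_count_scales_with_config(self, tiny_net_config):
        small = mf.count_parameters(mf.MSFFNet(tiny_net_config))[0]
        assert small == naive_msffn_param_count(
            stage_channels=tiny_net_config.stage_channels,
            stage_units=tiny_net_config.stage_units,
            fusing_channels=tiny_net_config.fusing_channels,
        )


class TestUNetBaseline:
    def test_output_contract_matches_proposed_model(self, rng):
        cfg = NetConfig(input_size=16, stage_channels=(3, 4, 5, 6, 7), seed=0)
        unet = mf.UNetBaseline(cfg, encoder_channels=(4, 6, 8, 10, 12))
        P = unet.forward(rng.normal(size=(2, 16, 16, 4)).astype(np.float32))
        assert P.shape == (2, 16, 16, 5)
        assert np.abs(P.sum(-1) - 1.0).max() < 1e-5

    def test_published_encoder_channels(self):
        assert mf.UNetBaseline.ENCODER_CHANNELS == (32, 64, 128, 256, 512)

    def test_baseline_larger_than_proposed(self):
        proposed = mf.count_parameters(mf.build_model())[1]
        baseline = mf.count_parameters(mf.build_unet_baseline())[1]
        assert baseline > proposed

    def test_baseline_trains_one_step(self, rng):
        cfg = NetConfig(input_size=16, stage_channels=(3, 4, 5, 6, 7),
                        dropout_rate=0.0, seed=0)
        unet = mf.UNetBaseline(cfg, encoder_channels=(3, 4, 5, 6, 7))
        x = rng.normal(size=(2, 16, 16, 4)).astype(np.float32)
        G = mf.one_hot(rng.integers(0, 5, (2, 16, 16)))
        loss_fn = LOSS_REGISTRY["ce"]
        opt = Adam(unet.params())
        v0, dP = loss_fn(unet.forward(x, training=True), G, None)
        opt.zero_grad()
        unet.backward(dP.astype(np.float32))
        opt.step(1e-3)
        v1, _ = loss_fn(unet.forward(x, training=True), G, None)
        assert v1 < v0


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tmp_path, tiny_net_config, rng):
        model = mf.MSFFNet(tiny_net_config)
        x = rng.normal(size=(1, 16, 16, 4)).astype(np.float32)
        before = model.forward(x)
        path = mf.save_checkpoint(model, tmp_path / "m.ckpt.npz")
        restored = mf.load_checkpoint(path)
        np.testing.assert_allclose(restored.forward(x), before, atol=0)

    def test_missing_checkpoint_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            mf.load_checkpoint(tmp_path / "nope.npz")
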