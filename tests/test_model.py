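"""Dense U-Net: channel bookkeeping, dense connectivity, shape contracts."""

import dataclasses

import numpy as np
import pytest

from denseunet.autograd import Tensor
from denseunet.containers import ValidationError
from denseunet.model import (
    SMALL_CONFIG,
    DenseBlock,
    DenseLayer,
    DenseUnetConfig,
    TransitionDown,
    build_denseunet,
    plan_channels,
    predict_labels,
)

RNG = np.random.default_rng(42)


class TestChannelPlan:
    def test_dense_block_arithmetic(self):
        spec = plan_channels(SMALL_CONFIG)
        add = SMALL_CONFIG.block_depth * SMALL_CONFIG.growth_rate
        for cin, cout in spec.encoder_blocks + spec.decoder_blocks + [spec.bottleneck]:
            assert cout == cin + add

    def test_transition_compression_floor(self):
        cfg = dataclasses.replace(SMALL_CONFIG, compression=0.37)
        spec = plan_channels(cfg)
        for cin, cout in spec.transitions:
            assert cout == int(np.floor(0.37 * cin))

    @pytest.mark.parametrize("seed", range(4))
    def test_plan_matches_traced_forward(self, seed):
        """Randomized configs: the computed plan equals observed channels."""
        rng = np.random.default_rng(seed)
        cfg = DenseUnetConfig(
            n_scales=int(rng.integers(2, 4)),
            block_depth=int(rng.integers(1, 4)),
            growth_rate=int(rng.integers(2, 10)),
            compression=float(rng.uniform(0.3, 1.0)),
            stem_channels=int(rng.integers(4, 12)),
            seed=seed,
        )
        spec = plan_channels(cfg)
        net = build_denseunet(cfg)
        div = 2 ** (cfg.n_scales - 1)
        x = Tensor(rng.normal(size=(1, 4, 2 * div, 2 * div)).astype(np.float32))

        observed = {}
        y = net.stem(x)
        assert y.shape[1] == spec.stem_out
        skips = []
        for i, (block, down) in enumerate(zip(net.enc_blocks, net.trans_down)):
            y = block(y)
            assert y.shape[1] == spec.encoder_blocks[i][1]
            skips.append(y)
            before = y.shape[2:]
            y = down(y)
            assert y.shape[1] == spec.transitions[i][1]
            assert y.shape[2:] == (before[0] // 2, before[1] // 2)
        y = net.bottleneck(y)
        assert y.shape[1] == spec.bottleneck[1]
        assert observed == {}

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError, match="compression"):
            plan_channels(dataclasses.replace(SMALL_CONFIG, compression=0.0))
        with pytest.raises(ValidationError, match="n_scales"):
            plan_channels(dataclasses.replace(SMALL_CONFIG, n_scales=1))
        with pytest.raises(ValidationError, match="block_depth"):
            plan_channels(dataclasses.replace(SMALL_CONFIG, block_depth=0))


class TestDenseLayer:
    def test_output_channels_equal_growth_rate(self):
        layer = DenseLayer(6, 5, RNG)
        out = layer(Tensor(np.ones((2, 6, 8, 8), dtype=np.float32)))
        assert out.shape == (2, 5, 8, 8)

    def test_eval_mode_deterministic_and_finite_on_zero_input(self):
        layer = DenseLayer(3, 4, RNG)
        for m in layer.modules():
            m.training = False
        x = Tensor(np.zeros((1, 3, 6, 6), dtype=np.float32))
        a, b = layer(x).data, layer(x).data
        np.testing.assert_array_equal(a, b)
        assert np.all(np.isfinite(a))


class TestDenseBlock:
    def test_concatenation_arithmetic_64_4_32(self):
        block = DenseBlock(64, 4, 32, np.random.default_rng(0))
        out = block(Tensor(np.random.default_rng(1).normal(size=(1, 64, 8, 8)).astype(np.float32)))
        assert out.shape[1] == 64 + 4 * 32  # 192

    def test_depth_one_is_input_plus_one_layer(self):
        block = DenseBlock(6, 1, 4, np.random.default_rng(0))
        x = Tensor(np.random.default_rng(1).normal(size=(1, 6, 8, 8)).astype(np.float32))
        out = block(x)
        assert out.shape[1] == 10
        np.testing.assert_array_equal(out.data[:, :6], x.data)  # [x0, x1] layout

    def test_true_dense_connectivity_vs_plain_chain(self):
        """Layer i must see all previous outputs, not only x_{i-1}."""
        block = DenseBlock(4, 3, 4, np.random.default_rng(3))
        for m in block.modules():
            m.training = False
        x = Tensor(np.random.default_rng(4).normal(size=(1, 4, 8, 8)).astype(np.float32))
        dense_out = block(x).data

        # plain-chain reference using the same layers: layer i gets only the
        # previous layer's output padded into the expected channel count
        from denseunet import autograd as ag

        feats = [x]
        prev = x
        for layer in block.dense_layers:
            need = layer.conv.in_ch
            if prev.shape[1] < need:
                pad = Tensor(np.zeros((1, need - prev.shape[1], 8, 8), dtype=np.float32))
                inp = ag.concat([prev, pad], axis=1)
            else:
                inp = prev
            prev = layer(inp)
            feats.append(prev)
        chain_out = ag.concat(feats, axis=1).data
        assert dense_out.shape == chain_out.shape
        assert not np.allclose(dense_out, chain_out)

    def test_information_flows_from_every_layer(self):
        """Zeroing layer j's conv weights changes all downstream outputs."""
        rng = np.random.default_rng(5)
        x = np.random.default_rng(6).normal(size=(1, 4, 8, 8)).astype(np.float32)
        base = DenseBlock(4, 3, 4, np.random.default_rng(7))
        for m in base.modules():
            m.training = False
        ref = base(Tensor(x)).data
        for j in range(3):
            block = DenseBlock(4, 3, 4, np.random.default_rng(7))
            for m in block.modules():
                m.training = False
            layer = block.dense_layers[j]
            layer.conv.weight.data = np.zeros_like(layer.conv.weight.data)
            layer.conv.bias.data = np.zeros_like(layer.conv.bias.data)
            out = block(Tensor(x)).data
            # positions downstream of j change; the block input passthrough does not
            assert not np.allclose(out, ref)
            np.testing.assert_array_equal(out[:, :4], ref[:, :4])


class TestTransition:
    def test_compression_and_pooling(self):
        td = TransitionDown(192, 96, RNG)
        out = td(Tensor(np.random.default_rng(1).normal(size=(1, 192, 16, 16)).astype(np.float32)))
        assert out.shape == (1, 96, 8, 8)

    def test_no_compression_keeps_channels(self):
        td = TransitionDown(12, 12, RNG)
        out = td(Tensor(np.ones((1, 12, 8, 8), dtype=np.float32)))
        assert out.shape == (1, 12, 4, 4)

    def test_constant_input_stays_constant_per_channel(self):
        td = TransitionDown(3, 2, np.random.default_rng(8))
        for m in td.modules():
            m.training = False
        out = td(Tensor(np.full((1, 3, 8, 8), 2.5, dtype=np.float32))).data
        # averaging a constant then 1x1 conv: each channel one constant value
        for ch in range(2):
            assert np.ptp(out[0, ch]) < 1e-5

    def test_odd_dims_rejected(self):
        td = TransitionDown(3, 2, RNG)
        with pytest.raises(ValueError, match="even"):
            td(Tensor(np.ones((1, 3, 7, 8), dtype=np.float32)))


class TestFullNetwork:
    def test_brats_input_shape_contract(self):
        """4x160x160 in, 4 class-probability maps of 160x160 out."""
        net = build_denseunet(dataclasses.replace(SMALL_CONFIG, n_scales=4))
        net.eval()
        out = net(Tensor(np.random.default_rng(0).normal(size=(1, 4, 160, 160)).astype(np.float32)))
        assert out.shape == (1, 4, 160, 160)
        np.testing.assert_allclose(out.data.sum(axis=1), 1.0, atol=1e-6)

    def test_probabilities_sum_to_one(self):
        net = build_denseunet(SMALL_CONFIG).eval()
        out = net(Tensor(np.random.default_rng(1).normal(size=(2, 4, 24, 24)).astype(np.float32)))
        np.testing.assert_allclose(out.data.sum(axis=1), 1.0, atol=1e-6)
        assert out.data.min() >= 0.0

    def test_indivisible_dims_error_names_divisor(self):
        net = build_denseunet(SMALL_CONFIG)
        with pytest.raises(ValidationError, match="divisible by 4"):
            net(Tensor(np.ones((1, 4, 30, 30), dtype=np.float32)))

    def test_construction_is_seed_reproducible(self):
        a = build_denseunet(SMALL_CONFIG)
        b = build_denseunet(SMALL_CONFIG)
        assert a.n_parameters() == b.n_parameters()
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)
        c = build_denseunet(dataclasses.replace(SMALL_CONFIG, seed=1))
        assert any(
            not np.array_equal(pa.data, pc.data)
            for pa, pc in zip(a.parameters(), c.parameters())
        )

    def test_nearest_upsample_variant_runs(self):
        cfg = dataclasses.replace(SMALL_CONFIG, upsample="nearest")
        net = build_denseunet(cfg).eval()
        out = net(Tensor(np.random.default_rng(2).normal(size=(1, 4, 16, 16)).astype(np.float32)))
        assert out.shape == (1, 4, 16, 16)


class TestPredictLabels:
    def test_untrained_network_yields_nested_masks(self):
        net = build_denseunet(SMALL_CONFIG)
        image = np.random.default_rng(3).normal(size=(4, 24, 24)).astype(np.float32)
        masks, labels = predict_labels(net, image)
        assert masks.is_nested()
        assert set(np.unique(labels).tolist()) <= {0, 1, 2, 4}

    def test_certain_class4_everywhere_gives_full_masks(self):
        net = build_denseunet(SMALL_CONFIG)
        # force the head to always pick the enhancing-tumor class
        net.head.weight.data = np.zeros_like(net.head.weight.data)
        net.head.bias.data = np.array([0, 0, 0, 50], dtype=np.float32)
        masks, labels = predict_labels(
            net, np.random.default_rng(4).normal(size=(4, 24, 24)).astype(np.float32)
        )
        assert masks.wt.all() and masks.tc.all() and masks.et.all()
        assert np.all(labels == 4)

    def test_deterministic_given_fixed_weights(self):
        net = build_denseunet(SMALL_CONFIG)
        image = np.random.default_rng(5).normal(size=(4, 24, 24)).astype(np.float32)
        _, l1 = predict_labels(net, image)
        _, l2 = predict_labels(net, image)
        np.testing.assert_array_equal(l1, l2)
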