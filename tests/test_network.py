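"""Dense backbone, SE attention, variants, and parameter accounting."""

import numpy as np
import pytest

from mfscnet.network import (
    ArchitectureSpec,
    SEBlock,
    apply_se_block,
    build_network,
    count_parameters,
    dense_block_forward,
    se_gate,
    se_parameter_overhead,
    squeeze_statistics,
    transition_forward,
)
from mfscnet.nn import Adam, Tensor, cross_entropy, no_grad, softmax
from mfscnet.nn.layers import Conv2d

TINY = dict(growth_rate=8, block_config=(2, 2, 2, 2), se_reduction=8, input_size=64)


class TestChannelBookkeeping:
    @pytest.mark.parametrize(
        "c_in,n_layers,k,c_out", [(64, 6, 32, 256), (128, 12, 32, 512), (16, 0, 8, 16)]
    )
    def test_dense_block_output_channels(self, c_in, n_layers, k, c_out):
        x = np.random.default_rng(0).normal(size=(c_in, 8, 8))
        out = dense_block_forward(x, n_layers, k, seed=1)
        assert out.shape == (c_out, 8, 8)
        if n_layers == 0:
            assert np.array_equal(out, x)

    def test_transition_compresses_and_halves(self):
        x = np.random.default_rng(0).normal(size=(256, 14, 14))
        out = transition_forward(x, 0.5, seed=1)
        assert out.shape == (128, 7, 7)
        out_full = transition_forward(x, 1.0, seed=1)
        assert out_full.shape == (256, 7, 7)

    def test_average_pooling_preserves_constants(self):
        from mfscnet.nn.tensor import avg_pool2d

        x = Tensor(np.full((1, 3, 6, 6), 2.5))
        assert np.allclose(avg_pool2d(x, 2, 2).data, 2.5)


class TestSqueezeStatistics:
    def test_constant_channel(self):
        x = np.full((1, 4, 4), 3.0)
        s = squeeze_statistics(x)
        assert s.global_mean[0] == 3.0 and s.local_max[0] == 3.0 and s.variance[0] == 0.0

    def test_two_by_two_enumeration(self):
        # channel {0,0,1,1}: mean 1/2, population variance 1/4, and the
        # single 2x2 average-pool cell is 1/2
        x = np.array([[[0.0, 0.0], [1.0, 1.0]]])
        s = squeeze_statistics(x)
        assert s.global_mean[0] == 0.5
        assert s.variance[0] == 0.25
        assert s.local_max[0] == 0.5

    def test_scaling_behaviour(self):
        rng = np.random.default_rng(7)
        x = np.abs(rng.normal(size=(3, 8, 8)))
        alpha = 2.7
        s1, s2 = squeeze_statistics(x), squeeze_statistics(alpha * x)
        assert np.allclose(s2.global_mean, alpha * s1.global_mean)
        assert np.allclose(s2.local_max, alpha * s1.local_max)
        assert np.allclose(s2.variance, alpha**2 * s1.variance)

    def test_stacked_descriptor_lengths(self):
        x = np.random.default_rng(0).normal(size=(5, 4, 4))
        s = squeeze_statistics(x)
        assert s.stacked(optimized=True).shape == (15,)
        assert s.stacked(optimized=False).shape == (5,)


class TestSEGate:
    def test_zero_weights_give_half_gates(self):
        block = SEBlock(8, reduction=4, optimized=True)
        for p in block.parameters():
            p.data[...] = 0.0
        stats = Tensor(np.random.default_rng(0).normal(size=(2, 24)))
        assert np.allclose(block.gates(stats).data, 0.5)

    def test_gates_strictly_in_unit_interval_and_length_c(self):
        x = np.random.default_rng(1).normal(size=(16, 6, 6))
        stats = squeeze_statistics(x)
        for optimized in (True, False):
            g = se_gate(stats, r=4, optimized=optimized, seed=3)
            assert g.shape == (16,)
            assert np.all((g > 0) & (g < 1))

    def test_tiny_channel_count_clamps_bottleneck_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            SEBlock(4, reduction=16)


class TestApplySEBlock:
    def test_identity_mode_passes_through(self):
        x = np.random.default_rng(2).normal(size=(2, 8, 5, 5))
        block = SEBlock(8, reduction=4, rng=np.random.default_rng(0))
        block.identity = True
        assert np.array_equal(apply_se_block(x, block), x)

    def test_matches_explicit_loop_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2, 6, 4, 4))
        block = SEBlock(6, reduction=2, rng=rng)
        out = apply_se_block(x, block)
        with no_grad():
            gates = block.gates(block._squeeze(Tensor(x))).data
        expect = np.empty_like(x)
        for n in range(2):
            for c in range(6):
                for i in range(4):
                    for j in range(4):
                        expect[n, c, i, j] = x[n, c, i, j] * gates[n, c]
        assert np.allclose(out, expect)

    def test_channel_mismatch_is_fatal(self):
        block = SEBlock(8, reduction=4)
        with pytest.raises(ValueError, match="channels"):
            apply_se_block(np.zeros((1, 4, 3, 3)), block)


class TestBuildNetwork:
    def test_forward_returns_normalized_class_scores(self):
        spec = ArchitectureSpec(variant="A", num_classes=3, **TINY)
        model = build_network(spec, seed=0).eval()
        x = np.random.default_rng(0).random((1, 3, 64, 64))
        with no_grad():
            scores = model(Tensor(x)).data
        assert scores.shape == (1, 3)
        assert abs(softmax(scores).sum() - 1.0) < 1e-6

    def test_full_size_forward_at_nominal_input(self):
        spec = ArchitectureSpec(variant="baseline", num_classes=2)
        model = build_network(spec, seed=0).eval()
        x = np.random.default_rng(1).random((1, 3, 224, 224))
        with no_grad():
            scores = model(Tensor(x)).data
        assert scores.shape == (1, 2)
        assert abs(softmax(scores).sum() - 1.0) < 1e-6

    def test_invalid_variant_is_fatal(self):
        with pytest.raises(ValueError, match="variant"):
            ArchitectureSpec(variant="D")

    def test_spec_serialization_round_trip(self):
        spec = ArchitectureSpec(variant="B", num_classes=8, **TINY)
        assert ArchitectureSpec.from_dict(spec.to_dict()) == spec

    def test_silencing_se_blocks_reproduces_baseline_exactly(self):
        """Variant A with identity SE blocks equals the baseline when the
        non-SE weights are shared."""
        spec_a = ArchitectureSpec(variant="A", num_classes=2, **TINY)
        spec_b = ArchitectureSpec(variant="baseline", num_classes=2, **TINY)
        a = build_network(spec_a, seed=0)
        base = build_network(spec_b, seed=1)
        se_param_ids = {
            id(p) for se in a.se_blocks() if se is not None for p in se.parameters()
        }
        shared = [p for p in a.parameters() if id(p) not in se_param_ids]
        base.load_state_arrays([p.data for p in shared])
        a.set_se_identity(True)
        x = np.random.default_rng(2).random((2, 3, 64, 64))
        a.eval(), base.eval()
        with no_grad():
            ya = a(Tensor(x)).data
            yb = base(Tensor(x)).data
        assert np.array_equal(ya, yb)

    def test_save_load_round_trip_preserves_outputs(self, tmp_path):
        from mfscnet.network import load_model, save_model

        spec = ArchitectureSpec(variant="C", num_classes=2, **TINY)
        model = build_network(spec, seed=4)
        # perturb BN running stats so the buffers are exercised too
        x = np.random.default_rng(5).random((4, 3, 64, 64))
        model.train()
        with no_grad():
            model(Tensor(x))
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        model.eval(), back.eval()
        with no_grad():
            ya = model(Tensor(x)).data
            yb = back(Tensor(x)).data
        assert np.array_equal(ya, yb)

    def test_single_training_step_decreases_loss(self):
        """One Adam step at the protocol learning rate reduces the loss on a
        fixed synthetic batch."""
        spec = ArchitectureSpec(variant="A", num_classes=2, **TINY)
        model = build_network(spec, seed=0)
        rng = np.random.default_rng(3)
        x = rng.random((8, 3, 64, 64))
        y = np.array([0, 1] * 4)
        opt = Adam(model.parameters(), lr=1e-4)
        model.train()
        loss0 = cross_entropy(model(Tensor(x)), y)
        loss0.backward()
        opt.step()
        loss1 = cross_entropy(model(Tensor(x)), y)
        assert float(loss1.data) < float(loss0.data)


class TestParameterCounts:
    def test_one_by_one_conv_closed_form(self):
        conv = Conv2d(3, 2, 1, bias=True)
        assert count_parameters(conv) == 3 * 2 + 2

    def test_plain_se_block_closed_form(self):
        # mean-only squeeze, C=128, r=16, biases: 128*8+8 + 8*128+128
        block = SEBlock(128, reduction=16, optimized=False)
        assert count_parameters(block) == 2184

    def test_baseline_matches_published_densenet121_total(self):
        """The reference 121-layer dense network has 7,978,856 trainable
        parameters with its native 1000-way classifier."""
        model = build_network(ArchitectureSpec(variant="baseline", num_classes=1000))
        assert count_parameters(model) == 7_978_856

    @pytest.mark.parametrize(
        "cfg",
        [
            dict(growth_rate=8, block_config=(2, 2, 2, 2), se_reduction=8),
            dict(growth_rate=12, block_config=(3, 4, 6, 4), se_reduction=4),
        ],
    )
    @pytest.mark.parametrize("num_classes", [2, 8])
    def test_se_overhead_additive_and_matches_closed_form(self, cfg, num_classes):
        counts = {}
        for variant in ("baseline", "A", "B", "C"):
            spec = ArchitectureSpec(variant=variant, num_classes=num_classes, **cfg)
            counts[variant] = count_parameters(build_network(spec))
            if variant != "baseline":
                assert counts[variant] - counts["baseline"] == se_parameter_overhead(spec)
        assert (counts["A"] - counts["baseline"]) == (
            counts["B"] - counts["baseline"]
        ) + (counts["C"] - counts["baseline"])

    def test_head_width_knob_changes_only_the_head(self):
        plain = build_network(ArchitectureSpec(variant="baseline", num_classes=2, **TINY))
        headed = build_network(
            ArchitectureSpec(variant="baseline", num_classes=2, head_width=100, **TINY)
        )
        c = plain.feature_channels
        expected_delta = (c * 100 + 100 + 100 * 2 + 2) - (c * 2 + 2)
        assert count_parameters(headed) - count_parameters(plain) == expected_delta
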