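import numpy as np
import pytest

from lodgeseg.network import (
    DSBlockSpec,
    NetworkSpec,
    analytic_param_count,
    build_mobile_unet,
    build_model,
    build_unet_baseline,
    count_trainable_params,
    ds_block,
    load_checkpoint,
    save_checkpoint,
)


class TestDSBlock:
    @pytest.mark.parametrize(
        "c_in,c_out,expected",
        [(64, 128, 9152), (3, 64, 353), (1, 1, 14)],
    )
    def test_parameter_formula(self, c_in, c_out, expected):
        # 9·c_in + c_in·c_out + 2·c_in + 2·c_out
        spec = DSBlockSpec(c_in, c_out)
        assert spec.param_count == expected
        block = ds_block(spec, np.random.default_rng(0))
        assert sum(p.size for p in block.parameters()) == expected

    def test_preserves_spatial_size(self):
        block = ds_block(DSBlockSpec(3, 8), np.random.default_rng(0))
        assert block.forward(np.zeros((1, 3, 10, 14), dtype=np.float32)).shape == (1, 8, 10, 14)

    def test_nonpositive_channels_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            DSBlockSpec(0, 4)


class TestSpec:
    def test_tile_must_be_divisible_by_16(self):
        with pytest.raises(ValueError, match="divisible"):
            NetworkSpec(tile=100)

    def test_decoder_mirrors_encoder(self):
        spec = NetworkSpec.variant("table1")
        assert spec.decoder_widths == (512, 256, 128, 64)

    def test_json_round_trip(self):
        spec = NetworkSpec.variant("text", in_channels=3, width_divisor=4, tile=64)
        assert NetworkSpec.from_json(spec.to_json()) == spec


class TestShapeContract:
    def test_table1_stage_shapes_at_tile_256_scaled(self):
        """Stage shapes follow the published architecture table; checked at
        width/4, tile 64 (exact 1/4 scaling of every Size row)."""
        spec = NetworkSpec.variant("table1", in_channels=4, width_divisor=4, tile=64)
        model = build_mobile_unet(spec, seed=0)
        x = np.zeros((1, 4, 64, 64), dtype=np.float32)
        model.forward(x, train=False)
        acts = model.activations
        assert acts["enc1"].shape == (1, 16, 64, 64)
        assert acts["enc2"].shape == (1, 32, 32, 32)
        assert acts["enc3"].shape == (1, 64, 16, 16)
        assert acts["enc4"].shape == (1, 128, 8, 8)
        assert acts["enc5"].shape == (1, 256, 4, 4)  # bottleneck = tile/16
        assert acts["dec1"].shape == (1, 128, 8, 8)
        assert acts["dec4"].shape == (1, 16, 64, 64)
        assert acts["logits"].shape == (1, 3, 64, 64)

    def test_full_width_bottleneck_is_16x16x1024(self):
        """Published bottleneck shape for 256×256 input, checked via the
        spatial contract: tile/16 with the full 1024-channel width."""
        spec = NetworkSpec.variant("table1", in_channels=4, tile=256)
        assert spec.tile // 16 == 16
        assert spec.encoder_widths[-1] == 1024
        # first skip concat: up1 output (512) + enc4 (512) = 1024 channels at 32×32
        assert spec.decoder_widths[0] + spec.encoder_widths[3] == 1024

    def test_softmax_head_normalizes_per_pixel(self):
        spec = NetworkSpec.variant("table1", in_channels=3, width_divisor=8, tile=32)
        model = build_mobile_unet(spec, seed=1)
        proba = model.predict_proba(np.random.default_rng(0).random((2, 3, 32, 32)).astype(np.float32))
        assert proba.sum(axis=1) == pytest.approx(np.ones((2, 32, 32)), abs=1e-5)

    def test_forward_determinism(self):
        spec = NetworkSpec.variant("table1", in_channels=3, width_divisor=8, tile=32)
        x = np.random.default_rng(5).random((1, 3, 32, 32)).astype(np.float32)
        a = build_mobile_unet(spec, seed=3).forward(x, train=False)
        b = build_mobile_unet(spec, seed=3).forward(x, train=False)
        assert np.array_equal(a, b)

    def test_channel_mismatch_rejected(self):
        spec = NetworkSpec.variant("table1", in_channels=4, width_divisor=8, tile=32)
        model = build_mobile_unet(spec, seed=0)
        with pytest.raises(ValueError, match="expected"):
            model.forward(np.zeros((1, 3, 32, 32), dtype=np.float32))


class TestParameterCounts:
    @pytest.mark.parametrize("variant", ["table1", "text", "double"])
    @pytest.mark.parametrize("in_channels", [3, 4])
    def test_introspection_equals_analytic_oracle_scaled(self, variant, in_channels):
        spec = NetworkSpec.variant(variant, in_channels=in_channels, width_divisor=8, tile=64)
        model = build_mobile_unet(spec, seed=0)
        assert count_trainable_params(model) == analytic_param_count(spec, "mobile_unet")

    def test_baseline_introspection_equals_analytic(self):
        spec = NetworkSpec.variant("table1", in_channels=4, width_divisor=8, tile=64)
        model = build_unet_baseline(spec, seed=0)
        assert count_trainable_params(model) == analytic_param_count(spec, "unet")

    def test_head_conv_count(self):
        # 1×1 conv 64→3 with bias: 64·3 + 3 = 195
        from lodgeseg.nn import Conv2d

        head = Conv2d(64, 3, 1, np.random.default_rng(0), bias=True)
        assert sum(p.size for p in head.parameters()) == 195

    def test_extra_input_channel_delta_is_analytic(self):
        """Going 3→4 channels touches only the first DS module:
        Δ = dw (9) + pw (c_out) + BN (2)."""
        for variant in ("table1", "double"):
            s3 = NetworkSpec.variant(variant, in_channels=3)
            s4 = NetworkSpec.variant(variant, in_channels=4)
            delta = analytic_param_count(s4) - analytic_param_count(s3)
            assert delta == 9 + s3.encoder_widths[0] + 2

    def test_mobile_unet_is_at_least_three_times_smaller_than_baseline(self):
        spec = NetworkSpec.variant("double", in_channels=4)
        mobile = analytic_param_count(spec, "mobile_unet")
        baseline = analytic_param_count(spec, "unet")
        assert mobile < baseline / 3

    def test_empty_model_counts_zero(self):
        from lodgeseg.nn import Sequential

        assert sum(p.size for p in Sequential().parameters()) == 0


class TestCheckpoint:
    def test_round_trip_preserves_outputs(self, tmp_path):
        spec = NetworkSpec.variant("table1", in_channels=3, width_divisor=8, tile=32)
        model = build_model("mobile_unet", spec, seed=9)
        x = np.random.default_rng(0).random((1, 3, 32, 32)).astype(np.float32)
        before = model.forward(x, train=False)
        save_checkpoint(model, tmp_path / "m.npz")
        restored = load_checkpoint(tmp_path / "m.npz")
        assert restored.spec == spec
        assert np.array_equal(restored.forward(x, train=False), before)
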