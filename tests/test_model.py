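import numpy as np
import pytest

from semgkit import nn
from semgkit.model import (
    LayerSpec,
    ModelConfig,
    VARIANTS,
    build_irdc_net,
    build_variant,
    count_parameters,
    layer_table,
)


@pytest.fixture(scope="module")
def small_config():
    return ModelConfig(n_classes=10, input_channels=1, input_length=512)


class TestBuild:
    def test_forward_pass_is_probability_simplex(self, small_config, rng):
        net = build_irdc_net(small_config, seed=0)
        x = rng.standard_normal((3, 1, 512)).astype(np.float32)
        probs = net.forward(x)
        assert probs.shape == (3, 10)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_output_dimension_tracks_block_configuration(self, rng):
        # 10-gesture protocol: two A blocks, one B block
        cfg = ModelConfig(n_classes=10, n_blocks_A=2, n_blocks_B=1, input_length=512)
        net = build_irdc_net(cfg)
        assert net.forward(rng.standard_normal((2, 1, 512)).astype(np.float32)).shape == (2, 10)
        names = [s.name for s in net.layer_specs]
        assert sum(n.endswith(".merge") and n.startswith("A") for n in names) == 2
        assert sum(n.endswith(".merge") and n.startswith("B") for n in names) == 1
        # 52-gesture benchmark scale: six A blocks, two B blocks
        cfg52 = ModelConfig(n_classes=52, n_blocks_A=6, n_blocks_B=2, input_length=512)
        net52 = build_irdc_net(cfg52)
        assert net52.forward(rng.standard_normal((1, 1, 512)).astype(np.float32)).shape == (1, 52)

    def test_too_short_input_names_minimum(self):
        with pytest.raises(ValueError, match="minimum"):
            ModelConfig(input_length=4)

    def test_seeded_build_is_reproducible(self, small_config, rng):
        x = rng.standard_normal((2, 1, 512)).astype(np.float32)
        a = build_irdc_net(small_config, seed=5).forward(x)
        b = build_irdc_net(small_config, seed=5).forward(x)
        np.testing.assert_array_equal(a, b)


class TestVariants:
    def test_baseline_has_no_shortcut_and_unit_dilations(self, small_config):
        net = build_variant(small_config, "baseline")
        convs = [s for s in net.layer_specs if s.kind == "conv"]
        assert all(c.dilation == 1 for c in convs)
        assert not any("shortcut" in s.name for s in net.layer_specs)
        assert not any("residual_add" in s.name for s in net.layer_specs)

    def test_full_keeps_shortcut_and_dilations(self, small_config):
        net = build_variant(small_config, "full")
        dilations = {s.dilation for s in net.layer_specs if s.kind == "conv"}
        assert 5 in dilations and 3 in dilations
        assert any("residual_add" in s.name for s in net.layer_specs)

    def test_residual_only_matches_full_parameter_count(self, small_config):
        full = build_variant(small_config, "full")
        res = build_variant(small_config, "residual_only")
        assert res.n_trainable() == full.n_trainable()

    def test_dilation_only_has_no_more_parameters_than_full(self, small_config):
        full = build_variant(small_config, "full")
        dil = build_variant(small_config, "dilation_only")
        assert dil.n_trainable() <= full.n_trainable()

    def test_unknown_variant_rejected(self, small_config):
        with pytest.raises(ValueError, match="variant"):
            build_variant(small_config, "bogus")


class TestParameterCount:
    def test_formula_examples(self):
        conv = LayerSpec(kind="conv", name="c", kernel=3, filters=16, in_channels=8)
        assert count_parameters([conv]) == 16 * (3 * 8 + 1) == 400
        dilated = LayerSpec(
            kind="conv", name="c", kernel=3, filters=16, in_channels=8, dilation=5
        )
        assert count_parameters([dilated]) == 400
        dense = LayerSpec(kind="dense", name="d", units_in=100, units_out=10)
        assert count_parameters([dense]) == 1010

    def test_incomplete_spec_rejected(self):
        with pytest.raises(ValueError, match="incomplete"):
            count_parameters([LayerSpec(kind="conv", name="c", kernel=3)])

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_table_count_equals_instantiated_count(self, small_config, variant):
        net = build_variant(small_config, variant)
        assert count_parameters(net.layer_specs) == net.n_trainable()

    def test_dilation_rates_do_not_change_count(self, small_config):
        from dataclasses import replace

        base = build_irdc_net(small_config).n_trainable()
        for da, db in [(1, 1), (2, 7), (9, 4)]:
            cfg = replace(small_config, dilation_A=da, dilation_B=db)
            assert build_irdc_net(cfg).n_trainable() == base

    def test_layer_table_renders_total(self, small_config):
        net = build_irdc_net(small_config)
        table = layer_table(net)
        assert str(net.n_trainable()) in table


class TestEngine:
    def test_leaky_relu_pointwise(self, rng):
        layer = nn.LeakyReLU(0.3)
        x = rng.standard_normal((4, 5)).astype(np.float32)
        y = layer.forward(x)
        np.testing.assert_allclose(y[x >= 0], x[x >= 0])
        np.testing.assert_allclose(y[x < 0], 0.3 * x[x < 0], rtol=1e-6)

    def test_conv_gradients_match_numerical(self, rng):
        layer = nn.Conv1D(2, 3, 4, stride=2, dilation=2, rng=rng, dtype=np.float64)
        x = rng.standard_normal((2, 2, 15))
        g = rng.standard_normal(layer.forward(x).shape)
        layer.w.grad[...] = 0
        gx = layer.backward(g)
        eps = 1e-6

        def scalar(arr, idx, val):
            old = arr[idx]
            arr[idx] = val
            out = float((layer.forward(x) * g).sum())
            arr[idx] = old
            return out

        for idx in [(0, 0, 0), (2, 1, 3), (1, 0, 2)]:
            num = (
                scalar(layer.w.value, idx, layer.w.value[idx] + eps)
                - scalar(layer.w.value, idx, layer.w.value[idx] - eps)
            ) / (2 * eps)
            assert layer.w.grad[idx] == pytest.approx(num, abs=1e-6)
        for idx in [(0, 0, 0), (1, 1, 7), (0, 1, 14)]:
            num = (
                scalar(x, idx, x[idx] + eps) - scalar(x, idx, x[idx] - eps)
            ) / (2 * eps)
            assert gx[idx] == pytest.approx(num, abs=1e-6)

    def test_dense_and_pool_shapes(self, rng):
        dense = nn.Dense(6, 4, rng=rng)
        assert dense.forward(np.ones((3, 6), dtype=np.float32)).shape == (3, 4)
        pool = nn.MaxPool1D(2)
        assert pool.forward(np.ones((2, 3, 9), dtype=np.float32)).shape == (2, 3, 4)

    def test_dropout_inference_is_identity(self, rng):
        drop = nn.Dropout(0.8, nn.RngBox(0))
        x = rng.standard_normal((5, 10)).astype(np.float32)
        np.testing.assert_array_equal(drop.forward(x, training=False), x)
        trained = drop.forward(x, training=True)
        assert (trained == 0).any()
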