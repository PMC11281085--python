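"""Fusion-network construction, shapes, gating ops, and parameter counts."""

import numpy as np
import pytest

from phubsense import (
    FusionNetwork,
    HazardFusionClassifier,
    ModelConfig,
    TrainConfig,
    count_parameters,
    expand_stats,
    glu_modulate,
    scaled_channels,
)
from phubsense.model import build_backbone
from phubsense.nn import Dense, softmax
from phubsense.train_eval import ABLATION_GRID, ablation_configs


def _batch(rng, n, cfg):
    out = {}
    if cfg.use_env:
        s = cfg.env_input_side
        out["env"] = rng.random((n, 3, s, s)).astype(np.float32)
    if cfg.use_gadf:
        s = cfg.gadf_input_side
        out["gadf"] = rng.random((n, 3, s, s)).astype(np.float32)
    if cfg.use_stats:
        out["stats"] = rng.random((n, cfg.stat_dim_in)).astype(np.float32)
    return out


class TestWidthFactor:
    @pytest.mark.parametrize("base, alpha, expected", [
        (32, 0.75, 24), (64, 0.75, 48), (1024, 0.75, 768),
        (1024, 1.0, 1024), (32, 0.1, 8),
    ])
    def test_channel_rounding(self, base, alpha, expected):
        assert scaled_channels(base, alpha) == expected


class TestBackbone:
    def test_thirteen_ds_units_and_x32_downsampling(self, rng):
        net, channels = build_backbone(1.0, np.random.default_rng(0))
        from phubsense.nn import DepthwiseConv2D

        ds_units = sum(isinstance(l, DepthwiseConv2D) for l in net.layers)
        assert ds_units == 13
        assert channels == 1024
        x = rng.random((1, 3, 64, 64)).astype(np.float32)
        assert net.forward(x).shape == (1, 1024, 2, 2)  # 64 / 32

    def test_width_factor_thins_final_channels(self):
        _, c = build_backbone(0.75, np.random.default_rng(0))
        assert c == 768

    def test_zero_input_gives_finite_output(self):
        net, _ = build_backbone(0.25, np.random.default_rng(0))
        out = net.forward(np.zeros((1, 3, 32, 32), np.float32))
        assert np.isfinite(out).all()


class TestFusionShapes:
    def test_small_config_shape_chain(self, small_model_config, rng):
        net = FusionNetwork(small_model_config)
        cap = {}
        logits = net.forward(_batch(rng, 2, small_model_config), capture=cap)
        assert cap["env_descriptor"] == 1024
        assert cap["motion_deep"] == scaled_channels(1024, 0.25)
        assert cap["stat_expanded"] == 16
        assert cap["joint"] == 1024 + cap["motion_deep"] + 16
        assert logits.shape == (2, 9)

    def test_batching_contract(self, small_model_config, rng):
        net = FusionNetwork(small_model_config)
        for n in (1, 4):
            assert net.forward(_batch(rng, n, small_model_config)).shape == (n, 9)

    def test_probabilities_sum_to_one(self, small_model_config, rng):
        net = FusionNetwork(small_model_config)
        p = net.predict_proba(_batch(rng, 8, small_model_config))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_eval_mode_is_deterministic(self, small_model_config, rng):
        net = FusionNetwork(small_model_config)
        b = _batch(rng, 3, small_model_config)
        np.testing.assert_array_equal(net.forward(b), net.forward(b))

    def test_missing_modality_raises(self, small_model_config, rng):
        net = FusionNetwork(small_model_config)
        b = _batch(rng, 2, small_model_config)
        del b["gadf"]
        with pytest.raises(ValueError, match="gadf"):
            net.forward(b)

    def test_wrong_stat_length_raises(self, small_model_config, rng):
        net = FusionNetwork(small_model_config)
        b = _batch(rng, 2, small_model_config)
        b["stats"] = b["stats"][:, :10]
        with pytest.raises(ValueError, match="stat vector"):
            net.forward(b)

    def test_input_side_not_divisible_by_32_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(base_resolution=100, beta=1.0).validate()

    def test_se_ratio_must_divide_joint_length(self, small_model_config):
        small_model_config.se_ratio = 7
        with pytest.raises(ValueError, match="se_ratio"):
            FusionNetwork(small_model_config)


class TestGatingOps:
    def test_expand_stats_output_length(self, rng):
        fc = Dense(63, 256, rng=rng)
        out = expand_stats(fc, rng.random(63))
        assert out.shape == (1, 256)
        with pytest.raises(ValueError):
            expand_stats(fc, rng.random(50))

    def test_expand_stats_zero_weights_give_zero(self):
        fc = Dense(63, 256)
        fc.params["w"][:] = 0
        fc.params["b"][:] = 0
        np.testing.assert_array_equal(expand_stats(fc, np.ones(63)), 0.0)

    def test_glu_zero_gate_halves_the_input(self, rng):
        x = rng.normal(size=(3, 16))
        out = glu_modulate(x, np.zeros((16, 16)), np.zeros(16))
        np.testing.assert_allclose(out, x / 2, atol=1e-12)

    def test_glu_saturated_gate_passes_the_input(self, rng):
        x = rng.normal(size=(2, 8))
        out = glu_modulate(x, np.zeros((8, 8)), np.full(8, 50.0))
        np.testing.assert_allclose(out, x, atol=1e-9)

    def test_glu_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            glu_modulate(rng.normal(size=(2, 8)), np.zeros((7, 7)), np.zeros(7))

    def test_se_weights_shrink_components(self, small_model_config, rng):
        net = FusionNetwork(small_model_config)
        net.forward(_batch(rng, 4, small_model_config))
        joint, w = net._joint, net._se_weights
        assert np.all((w > 0) & (w < 1))
        assert np.all(np.abs(joint * w) <= np.abs(joint) + 1e-12)


class TestParameterCount:
    def test_default_model_in_analytic_window(self):
        net = FusionNetwork(ModelConfig())
        assert 5_000_000 <= count_parameters(net) <= 9_000_000

    def test_count_is_static_across_forwards(self, small_model_config, rng):
        net = FusionNetwork(small_model_config)
        n0 = count_parameters(net)
        net.forward(_batch(rng, 2, small_model_config))
        assert count_parameters(net) == n0

    def test_width_factor_strictly_reduces_conv_parameters(self):
        full, _ = build_backbone(1.0, np.random.default_rng(0))
        thin, _ = build_backbone(0.75, np.random.default_rng(0))
        assert thin.n_params() < full.n_params()


class TestAblations:
    @pytest.mark.parametrize("name", list(ABLATION_GRID))
    def test_every_input_combination_builds_and_runs(self, name, small_model_config, rng):
        cfg = ablation_configs(small_model_config)[name]
        net = FusionNetwork(cfg)
        p = net.predict_proba(_batch(rng, 2, cfg))
        assert p.shape == (2, 9)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_all_modalities_disabled_rejected(self, small_model_config):
        small_model_config.use_env = False
        small_model_config.use_gadf = False
        small_model_config.use_stats = False
        with pytest.raises(ValueError):
            small_model_config.validate()


class TestClassifierEstimator:
    def _toy_data(self, rng, n=24):
        cfg = ModelConfig(alpha=0.25, beta=1.0, base_resolution=32,
                          gadf_input_side=32, se_ratio=8, stat_dim_out=16, seed=2)
        X = {
            "env": rng.random((n, 32, 32, 3)),
            "gadf": rng.random((n, 32, 32, 3)),
            "stats": rng.normal(size=(n, 63)),
        }
        y = np.array(["A", "B", "C"] * (n // 3))
        # make classes separable through the stats channel
        for i, lab in enumerate(y):
            X["stats"][i, :5] += {"A": -4, "B": 0, "C": 4}[lab]
        return cfg, X, y

    def test_fit_predict_roundtrip_and_determinism(self, rng):
        cfg, X, y = self._toy_data(rng)
        tc = TrainConfig(learning_rate=0.05, batch_size=8, epochs=4, seed=0)
        c1 = HazardFusionClassifier(cfg, tc).fit(X, y)
        c2 = HazardFusionClassifier(cfg, tc).fit(X, y)
        np.testing.assert_allclose(c1.predict_proba(X), c2.predict_proba(X), atol=1e-6)
        assert [h["train_loss"] for h in c1.history_] == [
            h["train_loss"] for h in c2.history_
        ]
        assert set(c1.predict(X)) <= {"A", "B", "C"}

    def test_divergence_aborts_with_diagnostic(self, rng):
        cfg, X, y = self._toy_data(rng)
        tc = TrainConfig(learning_rate=1e4, batch_size=8, epochs=3, seed=0)
        with pytest.raises((FloatingPointError, ValueError)):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                HazardFusionClassifier(cfg, tc).fit(X, y)

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = HazardFusionClassifier(ModelConfig(), TrainConfig())
        cloned = clone(est)
        assert cloned.config == est.config
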