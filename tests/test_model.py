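"""Architecture: encoder shapes, forward-pass oracles, parameter counting."""

import numpy as np
import pytest

from yieldnet import autodiff as ad
from yieldnet.model import (
    Batch,
    ConfigurationError,
    FeatureSpace,
    ModelConfig,
    _lstm_step,
    apply_feature_mask,
    count_parameters,
    model_forward,
    parameter_shapes,
    samples_to_batch,
    scnn_forward,
    wcnn_forward,
)
from yieldnet.preprocess import DimensionError
from yieldnet.training import init_params


def zero_params(config: ModelConfig):
    return {
        name: ad.parameter(np.zeros(shape))
        if name != "target.scale"
        else ad.tensor(np.array([1.0, 0.0]))
        for name, shape in parameter_shapes(config).items()
    }


def random_batch(config: ModelConfig, B: int, seed=0) -> Batch:
    rng = np.random.default_rng(seed)
    k = config.k
    return Batch(
        weather=rng.normal(size=(B, k, 6, 52)),
        soil=rng.normal(size=(B, k, 10, 9)),
        surface=rng.normal(size=(B, k, 4)),
        management=rng.normal(size=(B, k, config.n_mgmt_weeks)),
        avg_yield=rng.normal(size=(B, k)),
        target=rng.normal(size=B),
    )


class TestEncoders:
    @pytest.mark.parametrize("crop,expected", [("corn", 60), ("soybean", 40)])
    def test_weather_fc_width_by_crop(self, crop, expected):
        config = ModelConfig.for_crop(crop)
        params = init_params(config, 0)
        out = wcnn_forward(np.random.default_rng(0).normal(size=(3, 6, 52)), params, config)
        assert out.shape == (3, expected)
        assert np.isfinite(out.data).all()

    def test_soil_fc_width(self):
        config = ModelConfig.for_crop("corn")
        params = init_params(config, 0)
        out = scnn_forward(np.random.default_rng(0).normal(size=(2, 10, 9)), params, config)
        assert out.shape == (2, config.fc_soil_units)
        assert config.fc_soil_units == 40

    def test_zero_input_zero_params_gives_zero_output(self):
        config = ModelConfig.small()
        params = zero_params(config)
        w = wcnn_forward(np.zeros((2, 6, 52)), params, config)
        s = scnn_forward(np.zeros((2, 10, 9)), params, config)
        assert np.allclose(w.data, 0.0) and np.allclose(s.data, 0.0)

    @pytest.mark.parametrize("shape", [(2, 6, 50), (2, 5, 52), (6, 51)])
    def test_wrong_weather_shape_raises(self, shape):
        config = ModelConfig.small()
        params = init_params(config, 0)
        with pytest.raises(DimensionError):
            wcnn_forward(np.zeros(shape), params, config)

    def test_toy_conv_matches_manual_oracle(self):
        # one conv layer, one filter, known weights: compare against a
        # hand-rolled same-padding convolution plus stride-2 average pooling
        rng = np.random.default_rng(7)
        x = rng.normal(size=(1, 2, 8))
        w = rng.normal(size=(1, 2, 3))
        b = np.array([0.3])
        out = ad.avg_pool1d(ad.relu(ad.conv1d(ad.tensor(x), ad.tensor(w), ad.tensor(b))))
        xpad = np.pad(x[0], ((0, 0), (1, 1)))
        conv = np.array(
            [
                (xpad[:, j : j + 3] * w[0]).sum() + b[0]
                for j in range(8)
            ]
        )
        manual = np.maximum(conv, 0.0).reshape(4, 2).mean(axis=1)
        assert np.allclose(out.data[0, 0], manual, atol=1e-10)

    def test_pooling_lengths_follow_config(self):
        config = ModelConfig.for_crop("corn")
        assert config.conv_output_length("weather") == 3   # 52->26->13->6->3
        assert config.conv_output_length("soil") == 2      # 9->4->2


class TestForward:
    def test_prediction_matrix_shape(self, small_config):
        params = init_params(small_config, 0)
        batch = random_batch(small_config, 7)
        preds = model_forward(batch, params, small_config)
        assert preds.shape == (7, small_config.k)

    def test_zeroed_lstm_forces_constant_head_bias(self, small_config):
        params = zero_params(small_config)
        params["head.b"].data[:] = 42.0
        batch = random_batch(small_config, 4)
        preds = model_forward(batch, params, small_config)
        assert np.allclose(preds.data, 42.0)

    def test_single_unit_lstm_matches_manual_recurrence(self):
        # hand-set gates on a 2-step scalar input; oracle recurrence in numpy
        rng = np.random.default_rng(1)
        H, D = 1, 3
        params = {
            "lstm.wx": ad.parameter(rng.normal(size=(D, 4 * H))),
            "lstm.wh": ad.parameter(rng.normal(size=(H, 4 * H))),
            "lstm.b": ad.parameter(rng.normal(size=(4 * H,))),
        }
        xs = rng.normal(size=(2, 1, D))
        h = ad.tensor(np.zeros((1, H)))
        c = ad.tensor(np.zeros((1, H)))
        for t in range(2):
            h, c = _lstm_step(ad.tensor(xs[t]), h, c, params, H)

        def sig(v):
            return 1 / (1 + np.exp(-v))

        hn, cn = np.zeros(H), np.zeros(H)
        for t in range(2):
            z = xs[t, 0] @ params["lstm.wx"].data + hn @ params["lstm.wh"].data + params["lstm.b"].data
            i, f, g, o = z[0], z[1], z[2], z[3]
            cn = sig(f) * cn + sig(i) * np.tanh(g)
            hn = sig(o) * np.tanh(cn)
        assert np.allclose(h.data[0], hn, atol=1e-12)

    def test_forward_is_deterministic(self, small_config):
        params = init_params(small_config, 3)
        batch = random_batch(small_config, 5)
        a = model_forward(batch, params, small_config).data
        b = model_forward(batch, params, small_config).data
        assert np.array_equal(a, b)

    def test_batch_permutation_permutes_outputs(self, small_config):
        params = init_params(small_config, 3)
        batch = random_batch(small_config, 6)
        perm = np.array([3, 1, 5, 0, 2, 4])
        permuted = Batch(
            weather=batch.weather[perm],
            soil=batch.soil[perm],
            surface=batch.surface[perm],
            management=batch.management[perm],
            avg_yield=batch.avg_yield[perm],
            target=batch.target[perm],
        )
        a = model_forward(batch, params, small_config).data
        b = model_forward(permuted, params, small_config).data
        assert np.allclose(a[perm], b, atol=1e-12)

    def test_trend_only_prediction_ignores_zeroed_branches(self, small_config):
        # with weather/soil encoder weights zeroed, the forecast rides only
        # on the average-yield and management inputs
        params = init_params(small_config, 0)
        for name in params:
            if name.startswith(("wcnn", "wfc", "scnn", "sfc")):
                params[name].data[:] = 0.0
        batch = random_batch(small_config, 3)
        base = model_forward(batch, params, small_config).data
        perturbed = batch.copy()
        perturbed.weather += np.random.default_rng(9).normal(size=batch.weather.shape)
        perturbed.soil -= 1.7
        after = model_forward(perturbed, params, small_config).data
        assert np.array_equal(base, after)

    def test_k_mismatch_raises(self, small_config):
        params = init_params(small_config, 0)
        bad = random_batch(ModelConfig.small(k=3), 2)
        with pytest.raises(ConfigurationError):
            model_forward(bad, params, small_config)


class TestParameterCount:
    def test_dense_layer_arithmetic(self):
        params = {
            "w": ad.parameter(np.zeros((10, 5))),
            "b": ad.parameter(np.zeros(5)),
        }
        assert count_parameters(params) == 55

    def test_count_grows_with_lstm_width(self):
        small = count_parameters(init_params(ModelConfig.small(lstm_units=8), 0))
        large = count_parameters(init_params(ModelConfig.small(lstm_units=16), 0))
        assert large > small

    def test_default_corn_count_matches_shape_walk(self):
        config = ModelConfig.for_crop("corn")
        params = init_params(config, 0)

        # independent layer-by-layer recomputation
        def conv(cin, cout, k=3):
            return cout * cin * k + cout

        expected = 0
        cin = 6
        for f in (16, 32, 64, 128):
            expected += conv(cin, f)
            cin = f
        expected += 128 * 3 * 60 + 60  # weather FC after 52->3 pooling
        cin = 10
        for f in (16, 32, 64, 128):
            expected += conv(cin, f)
            cin = f
        expected += 128 * 2 * 40 + 40  # soil FC after 9->2 pooling
        step = 60 + 40 + 4 + 1 + 16
        H = 64
        expected += step * 4 * H + H * 4 * H + 4 * H  # LSTM
        expected += H + 1  # linear head
        assert count_parameters(params) == expected


class TestFeatureMask:
    def test_mask_zeroes_only_selected_features(self, small_config):
        space = FeatureSpace()
        batch = random_batch(small_config, 2)
        mask = np.ones(space.total, dtype=bool)
        mask[0] = False  # weather variable 0, week 0
        out = apply_feature_mask(batch, mask, space)
        assert np.allclose(out.weather[:, :, 0, 0], 0.0)
        assert np.array_equal(out.weather[:, :, 0, 1:], batch.weather[:, :, 0, 1:])
        assert np.array_equal(out.soil, batch.soil)

    def test_total_feature_count(self):
        assert FeatureSpace().total == 6 * 52 + 10 * 9 + 4 + 16
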