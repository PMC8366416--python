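import numpy as np
import pytest

from emgdecode.errors import ShapeError
from emgdecode.model import (ModelParams, conv_forward, count_parameters,
                             fc_forward, flatten_feature_map, forward,
                             forward_batch, init_model, load_model,
                             mse_loss_and_grads, save_model,
                             unflatten_feature_map)


class TestInit:
    def test_shapes(self):
        p = init_model(seed=0)
        assert p.conv_filters.shape == (6, 60)
        assert p.conv_biases.shape == (6,)
        assert p.fc_weights.shape == (3, 192)
        assert p.fc_biases.shape == (3,)

    def test_deterministic_given_seed(self):
        a, b = init_model(seed=4), init_model(seed=4)
        np.testing.assert_array_equal(a.conv_filters, b.conv_filters)
        np.testing.assert_array_equal(a.fc_weights, b.fc_weights)

    def test_different_seeds_differ(self):
        assert not np.array_equal(init_model(seed=1).conv_filters,
                                  init_model(seed=2).conv_filters)


class TestConvForward:
    def test_zero_input_zero_bias_gives_zero_map(self):
        p = init_model(seed=0)
        p.conv_biases[:] = 0.0
        fm = conv_forward(p, np.zeros((60, 32)))
        np.testing.assert_array_equal(fm, np.zeros((6, 32)))

    def test_output_shape_six_by_32(self, rng):
        fm = conv_forward(init_model(seed=1), rng.uniform(0, 1, (60, 32)))
        assert fm.shape == (6, 32)
        assert np.all(np.abs(fm) < 1.0)

    def test_all_ones_filter_saturates_to_tanh_60(self):
        p = init_model(seed=0)
        p.conv_filters[0, :] = 1.0
        p.conv_biases[0] = 0.0
        X = np.zeros((60, 32))
        X[:, 0] = 1.0
        fm = conv_forward(p, X)
        assert fm[0, 0] == pytest.approx(np.tanh(60.0))

    def test_matches_brute_force_dot_product(self, rng):
        p = init_model(seed=2)
        X = rng.uniform(0, 1, (60, 32))
        fm = conv_forward(p, X)
        for j in range(6):
            for c in range(32):
                expect = np.tanh(sum(p.conv_filters[j, t] * X[t, c] for t in range(60))
                                 + p.conv_biases[j])
                assert fm[j, c] == pytest.approx(expect, rel=1e-12)

    def test_no_channel_mixing(self, rng):
        p = init_model(seed=3)
        X = rng.uniform(0, 1, (60, 32))
        fm0 = conv_forward(p, X)
        X2 = X.copy()
        X2[:, 7] += 0.1
        fm1 = conv_forward(p, X2)
        diff = fm1 - fm0
        assert np.any(diff[:, 7] != 0.0)
        mask = np.ones(32, dtype=bool)
        mask[7] = False
        np.testing.assert_array_equal(diff[:, mask], 0.0)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ShapeError):
            conv_forward(init_model(seed=0), np.zeros((59, 32)))


class TestFcForward:
    def test_zero_feature_map_gives_biases(self):
        p = init_model(seed=0)
        np.testing.assert_allclose(fc_forward(p, np.zeros((6, 32))), p.fc_biases)

    def test_selector_weight_picks_one_feature(self, rng):
        p = init_model(seed=1)
        fm = rng.uniform(-0.9, 0.9, (6, 32))
        p.fc_weights[:] = 0.0
        p.fc_biases[:] = 0.0
        p.fc_weights[0, 37] = 1.0
        out = fc_forward(p, fm)
        assert out[0] == pytest.approx(flatten_feature_map(fm)[37])
        assert out[1] == out[2] == 0.0

    def test_matches_elementwise_sum_oracle(self, rng):
        p = init_model(seed=5)
        fm = rng.uniform(-1, 1, (6, 32))
        v = flatten_feature_map(fm)
        out = fc_forward(p, fm)
        for i in range(3):
            assert out[i] == pytest.approx(
                sum(p.fc_weights[i, k] * v[k] for k in range(192)) + p.fc_biases[i]
            )

    def test_linearity_doubling_weights_doubles_output(self, rng):
        p = init_model(seed=6)
        fm = rng.uniform(-1, 1, (6, 32))
        out1 = fc_forward(p, fm)
        p.fc_weights *= 2.0
        p.fc_biases *= 2.0
        np.testing.assert_allclose(fc_forward(p, fm), 2.0 * out1)


class TestForward:
    def test_output_lengths(self, rng):
        fm, angles = forward(init_model(seed=0), rng.uniform(0, 1, (60, 32)))
        assert angles.shape == (3,)
        assert flatten_feature_map(fm).shape == (192,)

    def test_flatten_order_is_feature_map_major_and_round_trips(self, rng):
        fm = rng.uniform(-1, 1, (6, 32))
        v = flatten_feature_map(fm)
        np.testing.assert_array_equal(v[:32], fm[0])
        np.testing.assert_array_equal(v[32:64], fm[1])
        np.testing.assert_array_equal(unflatten_feature_map(v, 6), fm)

    def test_batch_forward_matches_single(self, rng):
        p = init_model(seed=7)
        X = rng.uniform(0, 1, (5, 60, 32))
        fm_b, pred_b = forward_batch(p, X)
        for i in range(5):
            fm_i, pred_i = forward(p, X[i])
            np.testing.assert_allclose(fm_b[i], fm_i, atol=1e-14)
            np.testing.assert_allclose(pred_b[i], pred_i, atol=1e-12)


class TestCountParameters:
    def test_default_architecture_has_945(self):
        assert count_parameters(init_model(seed=0)) == 945

    def test_single_filter_variant_has_160(self):
        assert count_parameters(init_model(seed=0, n_filters=1)) == 160

    def test_count_invariant_under_reinit(self):
        assert count_parameters(init_model(seed=1)) == count_parameters(init_model(seed=99))

    def test_disabled_conv_bias_drops_six(self):
        assert count_parameters(init_model(seed=0, use_conv_bias=False)) == 939


class TestGradients:
    def test_analytic_gradients_match_central_differences(self, rng):
        p = init_model(seed=11)
        X = rng.uniform(0, 1, (3, 60, 32))
        y = rng.normal(0, 1, (3, 3))
        _, grads = mse_loss_and_grads(p, X, y)
        eps = 1e-6
        for name in ("conv_filters", "conv_biases", "fc_weights", "fc_biases"):
            arr = getattr(p, name)
            flat_idx = [tuple(i) for i in np.ndindex(arr.shape)]
            for idx in flat_idx[:: max(1, len(flat_idx) // 50)]:
                orig = arr[idx]
                arr[idx] = orig + eps
                lp, _ = mse_loss_and_grads(p, X, y)
                arr[idx] = orig - eps
                lm, _ = mse_loss_and_grads(p, X, y)
                arr[idx] = orig
                fd = (lp - lm) / (2 * eps)
                denom = max(abs(fd), abs(grads[name][idx]), 1e-6)
                assert abs(fd - grads[name][idx]) / denom < 1e-5, f"{name}{idx}"

    def test_frozen_conv_gradients_are_zero(self, rng):
        p = init_model(seed=12)
        X = rng.uniform(0, 1, (2, 60, 32))
        y = rng.normal(0, 1, (2, 3))
        _, grads = mse_loss_and_grads(p, X, y, freeze_conv=True)
        assert np.all(grads["conv_filters"] == 0.0)
        assert np.all(grads["conv_biases"] == 0.0)
        assert np.any(grads["fc_weights"] != 0.0)


class TestCheckpoint:
    def test_save_load_round_trip_is_bit_exact(self, tmp_path):
        p = init_model(seed=13)
        path = tmp_path / "model.npz"
        save_model(p, path)
        q = load_model(path)
        for name in ("conv_filters", "conv_biases", "fc_weights", "fc_biases"):
            np.testing.assert_array_equal(getattr(p, name), getattr(q, name))
        assert q.use_conv_bias == p.use_conv_bias and q.seed == p.seed

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ShapeError):
            ModelParams(np.zeros((6, 60)), np.zeros(5), np.zeros((3, 192)), np.zeros(3))
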