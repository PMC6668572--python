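"""Network: architecture construction, forward-pass contracts, the loss
pieces (softmax, cross-entropy, L2, dropout) and the analytic gradient."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from deepcytometry import network as nw
from deepcytometry.network import (ModelConfig, apply_dropout, build_network,
                                   cross_entropy, forward, l2_gradients,
                                   l2_penalty, one_hot, softmax)


def small_input_default():
    """Default conv/FC stack over a small spatial input (fits in memory)."""
    return ModelConfig(input_shape=(16, 32))


class TestBuildNetwork:
    def test_default_layer_counts(self):
        net = build_network(small_input_default())
        kinds = [s.kind for s in net.specs]
        assert kinds.count("conv3x3") == 16
        assert kinds.count("maxpool2x2") == 3
        assert kinds.count("dense") == 3

    def test_channel_progression_and_logit_width(self):
        cfg = small_input_default()
        channels = [p for _, p in cfg.conv_blocks]
        assert channels == sorted(channels)
        assert (channels[0], channels[-1]) == (16, 64)
        net = build_network(cfg)
        assert net.specs[-1].output_shape == (3,)

    def test_parameter_count_matches_shape_arithmetic(self):
        """Closed-form sum over layer shapes, computed independently."""
        cfg = ModelConfig(conv_blocks=((2, 8), (2, 16), (1, 32)),
                          fc_sizes=(64, 16, 3), input_shape=(16, 24))
        expected = 0
        in_ch, (h, w) = 1, cfg.input_shape
        for m, p in cfg.conv_blocks:
            for _ in range(m):
                expected += 3 * 3 * in_ch * p + p
                in_ch = p
            h, w = h // 2, w // 2
        n_in = h * w * in_ch
        for width in cfg.fc_sizes:
            expected += n_in * width + width
            n_in = width
        assert build_network(cfg).n_parameters == expected

    def test_input_too_small_for_pooling(self):
        with pytest.raises(ValueError):
            build_network(ModelConfig(input_shape=(4, 4)))


class TestForward:
    def test_output_shape(self, tiny_model_config, rng):
        net = build_network(tiny_model_config)
        h, w = tiny_model_config.input_shape
        out = forward(net, rng.normal(size=(5, h, w)))
        assert out.shape == (5, 3)

    def test_eval_mode_is_deterministic(self, rng):
        cfg = ModelConfig(conv_blocks=((1, 4), (1, 4), (1, 4)),
                          fc_sizes=(8, 3), dropout_keep_prob=0.5,
                          input_shape=(16, 16))
        net = build_network(cfg, seed=1)
        x = rng.normal(size=(4, 16, 16))
        assert np.array_equal(forward(net, x), forward(net, x))

    def test_train_mode_dropout_reproducible_from_seed(self, rng):
        cfg = ModelConfig(conv_blocks=((1, 4), (1, 4), (1, 4)),
                          fc_sizes=(8, 3), dropout_keep_prob=0.5,
                          input_shape=(16, 16))
        net = build_network(cfg, seed=1)
        x = rng.normal(size=(4, 16, 16))
        assert np.array_equal(forward(net, x, "train", seed=7),
                              forward(net, x, "train", seed=7))

    def test_zero_parameters_give_uniform_probabilities(self, tiny_model_config, rng):
        net = build_network(tiny_model_config)
        net.set_parameters({k: np.zeros_like(v)
                            for k, v in net.parameters().items()})
        h, w = tiny_model_config.input_shape
        logits = forward(net, rng.normal(size=(3, h, w)))
        assert np.allclose(logits, 0.0)
        assert np.allclose(softmax(logits), 1.0 / 3.0)

    def test_shape_mismatch_rejected(self, tiny_model_config, rng):
        net = build_network(tiny_model_config)
        with pytest.raises(ValueError):
            forward(net, rng.normal(size=(2, 5, 5)))


class TestSoftmax:
    def test_symmetric_logits(self):
        assert np.allclose(softmax(np.array([[0.0, 0.0, 0.0]])), 1 / 3)

    def test_analytic_example(self):
        p = softmax(np.array([np.log(2.0), 0.0, 0.0]))
        assert np.allclose(p, [0.5, 0.25, 0.25])

    @given(arrays(float, (20, 3), elements=st.floats(-50, 50)),
           st.floats(-100, 100))
    @settings(max_examples=250, derandomize=True, deadline=None)
    def test_rows_sum_to_one_and_shift_invariance(self, logits, shift):
        p = softmax(logits)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(p > 0)
        assert np.allclose(softmax(logits + shift), p, atol=1e-9)


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        probs = one_hot(np.array([0, 1, 2]))
        assert cross_entropy(probs, probs) == 0.0

    def test_uniform_is_log3(self):
        probs = np.full((5, 3), 1 / 3)
        labels = one_hot(np.zeros(5, dtype=int))
        assert cross_entropy(probs, labels) == pytest.approx(np.log(3))

    def test_hand_arithmetic(self):
        probs = np.array([[0.5, 0.3, 0.2], [0.25, 0.5, 0.25]])
        labels = one_hot(np.array([0, 0]))
        expected = (-np.log(0.5) - np.log(0.25)) / 2
        assert cross_entropy(probs, labels) == pytest.approx(expected)
        assert expected == pytest.approx(1.0397, abs=1e-4)

    def test_zero_probability_clamped_with_warning(self):
        probs = np.array([[0.0, 1.0, 0.0]])
        labels = one_hot(np.array([0]))
        with pytest.warns(RuntimeWarning):
            value = cross_entropy(probs, labels)
        assert np.isfinite(value)

    @given(arrays(float, (8, 3), elements=st.floats(-20, 20)),
           st.integers(0, 2))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_nonnegative_with_equality_iff_perfect(self, logits, label):
        probs = softmax(logits)
        labels = one_hot(np.full(8, label))
        ce = cross_entropy(probs, labels)
        assert ce >= 0.0
        if ce == 0.0:
            assert np.allclose(probs[:, label], 1.0)


class TestL2Penalty:
    def test_zero_parameters(self, tiny_model_config):
        net = build_network(tiny_model_config)
        net.set_parameters({k: np.zeros_like(v)
                            for k, v in net.parameters().items()})
        assert l2_penalty(net, 0.7) == 0.0

    def test_single_weight_arithmetic(self, tiny_model_config):
        net = build_network(tiny_model_config)
        params = {k: np.zeros_like(v) for k, v in net.parameters().items()}
        key = net.weight_keys()[0]
        params[key] = params[key].copy()
        params[key].flat[0] = 2.0
        net.set_parameters(params)
        assert l2_penalty(net, 0.5) == pytest.approx(2.0)  # 0.5 * 2^2

    def test_zero_multiplier(self, tiny_model_config):
        net = build_network(tiny_model_config, seed=5)
        assert l2_penalty(net, 0.0) == 0.0

    def test_biases_excluded_by_default(self, tiny_model_config):
        net = build_network(tiny_model_config, seed=5)
        params = net.parameters()
        for k in params:
            if k.endswith(".b"):
                params[k] += 10.0
        base = l2_penalty(net, 1.0)
        with_biases = l2_penalty(net, 1.0, include_biases=True)
        assert with_biases > base

    def test_gradient_matches_definition(self, tiny_model_config):
        net = build_network(tiny_model_config, seed=5)
        grads = l2_gradients(net, 0.3)
        params = net.parameters()
        for k, g in grads.items():
            assert np.allclose(g, 2 * 0.3 * params[k])


class TestDropout:
    def test_keep_prob_one_is_identity(self, rng):
        x = rng.normal(size=(10, 10))
        assert np.array_equal(apply_dropout(x, 1.0, "train", seed=0), x)
        assert np.array_equal(apply_dropout(x, 1.0, "eval"), x)

    def test_eval_mode_is_identity(self, rng):
        x = rng.normal(size=(10, 10))
        assert np.array_equal(apply_dropout(x, 0.3, "eval"), x)

    def test_train_mode_preserves_mean(self):
        """Inverted scaling: the expectation over masks equals the input."""
        x = np.ones(10_000)
        out = apply_dropout(x, 0.7, "train", seed=123)
        assert out.mean() == pytest.approx(1.0, rel=0.02)

    def test_invalid_keep_prob(self):
        with pytest.raises(ValueError):
            apply_dropout(np.ones(3), 0.0, "train", seed=0)


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self, rng):
        """Full backward pass (cross-entropy + L2) vs central differences."""
        cfg = ModelConfig(conv_blocks=((1, 2), (1, 2), (1, 3)),
                          fc_sizes=(5, 3), input_shape=(8, 8),
                          dropout_keep_prob=1.0, l2_multiplier=0.01)
        net = build_network(cfg, seed=3)
        X = rng.normal(size=(3, 8, 8))
        y1 = one_hot(np.array([0, 1, 2]))

        def loss():
            return (cross_entropy(softmax(net.forward(X)), y1)
                    + l2_penalty(net, cfg.l2_multiplier))

        probs = softmax(net.forward(X))
        net.backward((probs - y1) / 3)
        grads = net.gradients()
        for k, g in l2_gradients(net, cfg.l2_multiplier).items():
            grads[k] = grads[k] + g

        params = net.parameters()
        for key, arr in params.items():
            flat = arr.ravel()
            idx = rng.choice(flat.size, size=min(6, flat.size), replace=False)
            for i in idx:
                eps = 1e-6
                old = flat[i]
                flat[i] = old + eps
                lp = loss()
                flat[i] = old - eps
                lm = loss()
                flat[i] = old
                numeric = (lp - lm) / (2 * eps)
                analytic = grads[key].ravel()[i]
                denom = max(1e-6, abs(numeric) + abs(analytic))
                assert abs(numeric - analytic) / denom < 1e-4, key
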