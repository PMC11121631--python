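import numpy as np
import pytest

from n1loc.n1nn_core import (N1NNConfig, apply_gradients, backward, forward,
                             init_params, loss)
from n1loc.records import LocalizationClass

from conftest import random_onehot


def finite_difference_gradients(params, x, config, target, h=1e-5):
    """Central-difference oracle for the loss gradient (independent of backward)."""
    grads = []
    for w in params.arrays():
        g = np.zeros_like(w)
        it = np.nditer(w, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = w[idx]
            w[idx] = orig + h
            lp = loss(forward(params, x, config), target)
            w[idx] = orig - h
            lm = loss(forward(params, x, config), target)
            w[idx] = orig
            g[idx] = (lp - lm) / (2 * h)
        grads.append(g)
    return grads


class TestInitParams:
    def test_same_seed_is_bit_identical_different_seed_differs(self, tiny_config):
        p1, p2 = init_params(tiny_config, 5), init_params(tiny_config, 5)
        p3 = init_params(tiny_config, 6)
        for a, b in zip(p1.arrays(), p2.arrays()):
            np.testing.assert_array_equal(a, b)
        assert any((a != b).any() for a, b in zip(p1.arrays(), p3.arrays()))

    def test_shapes_match_config(self):
        cfg = N1NNConfig(c=2, gamma=3, n_hidden_kernels=2, input_width=22,
                         kernel_hidden_units=5, state_units=4, fc_hidden_units=6)
        p = init_params(cfg, 0)
        assert p.input_kernel.w1.shape == ((2 * 2 + 1) * 22, 5)
        assert p.input_kernel.w2.shape == (5, 4)
        assert len(p.hidden_kernels) == 2
        for k in p.hidden_kernels:
            assert k.w1.shape == ((2 * 3 + 1) * 4, 5)
            assert k.w2.shape == (5, 4)
        assert p.fc_w1.shape == (4, 6) and p.fc_w2.shape == (6, 8)

    def test_biases_zero_and_weights_within_glorot_bound(self, tiny_config):
        p = init_params(tiny_config, 0)
        assert not p.input_kernel.b1.any() and not p.fc_b2.any()
        w = p.input_kernel.w1
        r = np.sqrt(6.0 / (w.shape[0] + w.shape[1]))
        assert (np.abs(w) <= r).all()


class TestForward:
    def test_zero_weights_give_uniform_class_probabilities(self, tiny_config, rng):
        params = init_params(tiny_config, 0)
        for a in params.arrays():
            a[:] = 0.0
        x = random_onehot(rng, 12)
        probs = forward(params, x, tiny_config).probabilities
        np.testing.assert_allclose(probs, np.full(8, 0.125), atol=1e-12)

    @pytest.mark.parametrize("n", [1, 30, 500])
    def test_output_dimension_is_length_invariant(self, tiny_config, tiny_params, rng, n):
        x = random_onehot(rng, n)
        trace = forward(tiny_params, x, tiny_config)
        assert trace.probabilities.shape == (8,)
        assert trace.pooled.shape == (tiny_config.state_units,)

    def test_probabilities_lie_on_the_simplex(self, tiny_config, tiny_params, rng):
        for n in (3, 17, 64):
            p = forward(tiny_params, random_onehot(rng, n), tiny_config).probabilities
            assert abs(p.sum() - 1.0) < 1e-9
            assert (p >= 0).all()

    def test_constant_rows_pool_identically_regardless_of_length(self):
        cfg = N1NNConfig(c=0, gamma=0, n_hidden_kernels=1, input_width=22,
                         kernel_hidden_units=4, state_units=3, fc_hidden_units=4)
        params = init_params(cfg, 9)
        row = np.zeros(22)
        row[5] = 1.0
        t1 = forward(params, np.tile(row, (10, 1)), cfg)
        t2 = forward(params, np.tile(row, (20, 1)), cfg)
        np.testing.assert_allclose(t1.pooled, t2.pooled, atol=1e-15)
        np.testing.assert_allclose(t1.probabilities, t2.probabilities, atol=1e-15)

    def test_width_mismatch_rejected(self, tiny_config, tiny_params, rng):
        with pytest.raises(ValueError, match="width"):
            forward(tiny_params, rng.random((5, 21)), tiny_config)

    def test_pooled_vector_is_mean_of_last_kernel_states(self, tiny_config,
                                                         tiny_params, rng):
        trace = forward(tiny_params, random_onehot(rng, 11), tiny_config)
        np.testing.assert_allclose(trace.pooled,
                                   trace.kernel_states[-1].mean(axis=0))


class TestLoss:
    def test_uniform_prediction_costs_log8(self, tiny_config, rng):
        params = init_params(tiny_config, 0)
        for a in params.arrays():
            a[:] = 0.0
        trace = forward(params, random_onehot(rng, 5), tiny_config)
        assert loss(trace, LocalizationClass.Nucleus) == pytest.approx(np.log(8))

    def test_loss_is_monotone_in_target_probability(self, tiny_config, tiny_params, rng):
        trace = forward(tiny_params, random_onehot(rng, 8), tiny_config)
        losses = [loss(trace, c) for c in LocalizationClass]
        order_by_prob = np.argsort(-trace.probabilities)
        assert sorted(range(8), key=lambda i: losses[i]) == list(order_by_prob)


class TestBackward:
    def test_matches_finite_differences_on_all_parameter_groups(self):
        cfg = N1NNConfig(c=1, gamma=1, n_hidden_kernels=1, input_width=5,
                         kernel_hidden_units=4, state_units=3, fc_hidden_units=4)
        params = init_params(cfg, 1)
        rng = np.random.default_rng(2)
        x = rng.random((7, 5))
        target = LocalizationClass.Membrane
        trace = forward(params, x, cfg)
        analytic = backward(params, trace, target).arrays()
        numeric = finite_difference_gradients(params, x, cfg, target)
        max_rel = 0.0
        for a, n in zip(analytic, numeric):
            # denominator floored at the central-difference noise scale so
            # near-zero entries are compared absolutely, not by ratio
            denom = np.maximum(np.maximum(np.abs(a), np.abs(n)), 1e-4)
            max_rel = max(max_rel, float(np.max(np.abs(a - n) / denom)))
        assert max_rel < 1e-5

    def test_stale_trace_is_detected(self, tiny_config, tiny_params, rng):
        x = random_onehot(rng, 6)
        trace = forward(tiny_params, x, tiny_config)
        grads = backward(tiny_params, trace, LocalizationClass.Other)
        apply_gradients(tiny_params, grads, learning_rate=0.01)
        with pytest.raises(ValueError, match="stale"):
            backward(tiny_params, trace, LocalizationClass.Other)

    def test_gradient_vanishes_when_target_probability_is_one(self, tiny_config,
                                                              tiny_params, rng):
        x = random_onehot(rng, 6)
        trace = forward(tiny_params, x, tiny_config)
        # force a delta distribution on the target class
        trace.probabilities[:] = 0.0
        trace.probabilities[2] = 1.0
        grads = backward(tiny_params, trace, LocalizationClass.GolgiApparatus)
        assert all(not g.any() for g in grads.arrays())


class TestLayerAccounting:
    @pytest.mark.parametrize("k,expected", [(0, 3), (1, 5), (2, 7), (4, 11)])
    def test_hidden_layer_count_is_3_plus_2k(self, k, expected):
        cfg = N1NNConfig(n_hidden_kernels=k)
        assert cfg.n_hidden_layers == expected

    def test_window_sizes_follow_semi_contexts(self):
        cfg = N1NNConfig(c=5, gamma=8)
        assert cfg.input_window == 11 and cfg.hidden_window == 17

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            N1NNConfig(c=-1)
        with pytest.raises(ValueError):
            N1NNConfig(state_units=0)
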