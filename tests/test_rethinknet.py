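import numpy as np
import pytest

from toxmlpath.datamodel import MultiLabelDataset, ValidationError
from toxmlpath.rethinknet import (
    AttRethinkNet,
    ConfigurationError,
    RethinkConfig,
    build_model,
    label_weight_vector,
    predict,
    train,
)

from conftest import random_dataset


def _tiny_cfg(**kw):
    kw.setdefault("T", 3)
    kw.setdefault("hidden_units", 4)
    kw.setdefault("epochs", 2)
    kw.setdefault("seed", 1)
    return RethinkConfig(**kw)


class TestBuildAndShapes:
    def test_output_shape_and_sigmoid_range(self, rng):
        m = build_model(RethinkConfig(T=5, hidden_units=8, seed=0), dim=10, L=4)
        scores = m.forward(rng.normal(size=(3, 10)))
        assert scores.shape == (3, 5, 4)
        assert ((scores > 0) & (scores < 1)).all()

    def test_parameter_count_invariant_to_T(self):
        m3 = build_model(RethinkConfig(T=3, hidden_units=8, seed=0), dim=10, L=4)
        m5 = build_model(RethinkConfig(T=5, hidden_units=8, seed=0), dim=10, L=4)
        assert m3.parameter_count() == m5.parameter_count()

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ConfigurationError):
            build_model(_tiny_cfg(), dim=10, L=0)
        with pytest.raises(ConfigurationError):
            build_model(_tiny_cfg(), dim=0, L=2)

    def test_invalid_config_fields_named(self):
        with pytest.raises(ConfigurationError, match="T"):
            RethinkConfig(T=0)
        with pytest.raises(ConfigurationError, match="cell"):
            RethinkConfig(cell="gru")
        with pytest.raises(ConfigurationError, match="threshold"):
            RethinkConfig(threshold=1.5)

    @pytest.mark.parametrize("cell", ["lstm", "srn"])
    @pytest.mark.parametrize("attention", ["feature_axis", "step_axis", "off"])
    def test_shape_contract_across_modes(self, rng, cell, attention):
        cfg = _tiny_cfg(cell=cell, attention=attention)
        m = build_model(cfg, dim=6, L=3)
        scores = m.forward(rng.normal(size=(4, 6)))
        assert scores.shape == (4, 3, 3)
        assert ((scores > 0) & (scores < 1)).all()


class TestAttention:
    def test_zero_initialized_dense_gives_uniform_weights(self, rng):
        m = build_model(_tiny_cfg(), dim=8, L=2)
        m.params["W_a"][:] = 0.0
        m.params["b_a"][:] = 0.0
        a = m.attention_probabilities(rng.normal(size=(5, 8)))
        np.testing.assert_allclose(a, 1.0 / 8, atol=1e-12)

    def test_weights_sum_to_one(self, rng):
        m = build_model(_tiny_cfg(), dim=8, L=2)
        a = m.attention_probabilities(rng.normal(size=(5, 8)))
        np.testing.assert_allclose(a.sum(axis=1), 1.0, atol=1e-6)
        assert (a >= 0).all()

    def test_inference_deterministic(self, rng):
        m = build_model(_tiny_cfg(), dim=8, L=2)
        X = rng.normal(size=(5, 8))
        np.testing.assert_array_equal(
            m.attention_probabilities(X), m.attention_probabilities(X)
        )

    def test_off_mode_raises(self, rng):
        m = build_model(_tiny_cfg(attention="off"), dim=4, L=2)
        with pytest.raises(ConfigurationError):
            m.attention_probabilities(rng.normal(size=(2, 4)))

    def test_block_output_is_input_times_weights(self, rng):
        # the multiply layer applies the mean-1 rescaled probabilities
        m = build_model(_tiny_cfg(), dim=6, L=2)
        X = rng.normal(size=(3, 6))
        a = m.attention_probabilities(X)
        x_steps, _ = m._attention_forward(X)
        expected = X * (6 * a)
        for t in range(m.cfg.T):
            np.testing.assert_allclose(x_steps[:, t, :], expected, atol=1e-12)

    def test_step_axis_weights_normalized_over_steps(self, rng):
        m = build_model(_tiny_cfg(attention="step_axis"), dim=5, L=2)
        a = m.attention_probabilities(rng.normal(size=(4, 5)))
        assert a.shape == (4, 5, 3)
        np.testing.assert_allclose(a.sum(axis=2), 1.0, atol=1e-6)

    def test_attention_off_equals_plain_path_with_copied_weights(self, rng):
        att = build_model(_tiny_cfg(attention="feature_axis"), dim=6, L=2)
        off = build_model(_tiny_cfg(attention="off"), dim=6, L=2)
        for k in ("W_x", "W_h", "b", "W_y", "b_y"):
            off.params[k] = att.params[k].copy()
        # force uniform attention: mean-1 rescaled weights become exactly 1
        att.params["W_a"][:] = 0.0
        att.params["b_a"][:] = 0.0
        X = rng.normal(size=(4, 6))
        np.testing.assert_allclose(att.forward(X), off.forward(X), atol=1e-12)


class TestGradients:
    @pytest.mark.parametrize("cell", ["lstm", "srn"])
    @pytest.mark.parametrize("attention", ["feature_axis", "step_axis", "off"])
    def test_backprop_matches_numerical_gradient(self, rng, cell, attention):
        cfg = _tiny_cfg(cell=cell, attention=attention)
        m = build_model(cfg, dim=5, L=3)
        X = rng.normal(size=(6, 5))
        Y = rng.integers(0, 2, (6, 3)).astype(float)
        w = np.array([0.5, 1.0, 1.5])
        scores, cache = m.forward(X, with_cache=True)
        grads = m._backward(X, Y, scores, cache, w)
        eps = 1e-6
        for key in m.params:
            p = m.params[key]
            flat = p.reshape(-1)
            idxs = rng.choice(flat.size, size=min(8, flat.size), replace=False)
            for i in idxs:
                old = flat[i]
                flat[i] = old + eps
                lp = m.loss(X, Y, w)
                flat[i] = old - eps
                lm = m.loss(X, Y, w)
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                assert grads[key].reshape(-1)[i] == pytest.approx(num, abs=1e-6, rel=1e-4)


class TestTraining:
    def test_epoch1_loss_reproducible(self, rng):
        ds = random_dataset(rng, n=20, dim=5, L=3)
        cfg = _tiny_cfg(epochs=1)
        _, h1 = train(build_model(cfg, 5, 3), ds, cfg)
        _, h2 = train(build_model(cfg, 5, 3), ds, cfg)
        assert h1[0] == h2[0]

    def test_history_length_equals_epochs(self, rng):
        ds = random_dataset(rng, n=20, dim=5, L=3)
        cfg = _tiny_cfg(epochs=3)
        _, hist = train(build_model(cfg, 5, 3), ds, cfg)
        assert len(hist) == 3

    def test_uniform_weights_balanced_labels_reduce_to_plain_bce(self, rng):
        m = build_model(_tiny_cfg(label_weights="uniform"), dim=4, L=2)
        X = rng.normal(size=(6, 4))
        Y = rng.integers(0, 2, (6, 2)).astype(float)
        scores = m.forward(X)
        eps = 1e-12
        s = np.clip(scores, eps, 1 - eps)
        plain = float(
            -(Y[:, None, :] * np.log(s) + (1 - Y[:, None, :]) * np.log(1 - s)).mean()
        )
        assert m.loss(X, Y, np.ones(2)) == pytest.approx(plain, abs=1e-12)

    def test_dataset_dim_mismatch_rejected(self, rng):
        ds = random_dataset(rng, n=10, dim=5, L=3)
        m = build_model(_tiny_cfg(), dim=4, L=3)
        with pytest.raises(ValidationError):
            train(m, ds, m.cfg)


class TestLabelWeights:
    def test_inverse_frequency_mean_one(self, rng):
        Y = rng.integers(0, 2, (40, 5))
        Y[:, 0] = 1
        w = label_weight_vector(RethinkConfig(), Y)
        assert w.mean() == pytest.approx(1.0, abs=1e-12)
        assert (w > 0).all()

    def test_rarer_label_weighs_more(self):
        Y = np.zeros((20, 2), dtype=int)
        Y[:10, 0] = 1
        Y[:2, 1] = 1
        w = label_weight_vector(RethinkConfig(), Y)
        assert w[1] > w[0]

    def test_zero_count_label_clamped(self):
        Y = np.zeros((20, 2), dtype=int)
        Y[:10, 0] = 1
        w = label_weight_vector(RethinkConfig(weight_cap=5.0), Y)
        assert np.isfinite(w).all()

    def test_explicit_vector_passthrough(self):
        Y = np.zeros((4, 3), dtype=int)
        Y[0] = 1
        cfg = RethinkConfig(label_weights=np.array([1.0, 2.0, 3.0]))
        np.testing.assert_array_equal(label_weight_vector(cfg, Y), [1.0, 2.0, 3.0])


class TestPredict:
    def test_trace_length_and_threshold(self, rng):
        ds = random_dataset(rng, n=15, dim=5, L=3)
        cfg = _tiny_cfg(T=4, epochs=1)
        m, _ = train(build_model(cfg, 5, 3), ds, cfg)
        trace = predict(m, ds.features)
        assert trace.scores.shape == (15, 4, 3)
        np.testing.assert_array_equal(
            trace.final_labels, (trace.scores[:, -1, :] >= 0.5).astype(int)
        )

    def test_dim_mismatch_rejected(self, rng):
        m = build_model(_tiny_cfg(), dim=5, L=3)
        with pytest.raises(ValidationError):
            predict(m, rng.normal(size=(3, 4)))
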