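"""Classifier architecture, gradients, training contracts."""

import numpy as np
import pytest

from deepmethyl import (
    ModelConfig,
    TrainConfig,
    ValidationError,
    build_model,
    predict,
    train,
)
from deepmethyl._nn import softmax_cross_entropy
from deepmethyl.model import MethylationClassifier

TINY = dict(input_len=5, input_dim=4, conv_filters=2, n_heads=2,
            n_encoder_layers=1, ffn_dim=7, fc_dims=(6, 4))


class TestArchitecture:
    def test_output_rows_are_probability_distributions(self, rng):
        m = build_model(ModelConfig(**TINY, seed=0))
        logits = m.forward(rng.normal(size=(8, 5, 4)))
        probs = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
        assert probs.shape == (8, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_concatenated_width_is_branches_times_filters(self):
        cfg = ModelConfig(input_len=39, input_dim=16, conv_filters=8, n_heads=4)
        assert cfg.width == 3 * 8
        m = build_model(cfg)
        # the encoder operates on the concatenated width
        assert m.encoder[0].mha.params["Wq"].shape == (24, 24)

    def test_width_not_divisible_by_heads_rejected(self):
        with pytest.raises(ValidationError):
            ModelConfig(input_len=5, input_dim=4, conv_filters=3, n_heads=4)

    def test_parameter_count_invariant_to_batch_and_sample_count(self, rng):
        m = build_model(ModelConfig(**TINY, seed=1))
        n0 = m.n_parameters()
        m.forward(rng.normal(size=(2, 5, 4)))
        m.forward(rng.normal(size=(17, 5, 4)))
        assert m.n_parameters() == n0 == build_model(ModelConfig(**TINY, seed=9)).n_parameters()

    def test_forward_is_finite_for_random_inputs(self, rng):
        m = build_model(ModelConfig(**TINY, seed=2))
        logits = m.forward(rng.normal(scale=3.0, size=(1000, 5, 4)))
        assert np.isfinite(logits).all()

    def test_shape_mismatch_rejected(self, rng):
        m = build_model(ModelConfig(**TINY, seed=0))
        with pytest.raises(ValidationError):
            m.forward(rng.normal(size=(2, 6, 4)))


class TestGradients:
    def test_backprop_matches_central_differences(self, rng):
        cfg = ModelConfig(**TINY, dropout_rate=0.0, seed=3)
        m = build_model(cfg)
        # jitter every parameter so no ReLU sits exactly at its kink, where
        # central differences and the subgradient legitimately disagree
        for layer in m.param_layers():
            for k in layer.params:
                layer.params[k] = layer.params[k] + rng.normal(
                    scale=0.05, size=layer.params[k].shape
                )
        X = rng.normal(size=(3, 5, 4))
        y = np.array([0, 1, 1])

        def loss_fn():
            return softmax_cross_entropy(m.forward(X, train=True), y)[0]

        logits = m.forward(X, train=True)
        _, dlogits, _ = softmax_cross_entropy(logits, y)
        m.backward(dlogits)

        eps = 1e-6
        for layer in m.param_layers():
            for k, v in layer.params.items():
                flat = v.ravel()
                dflat = layer.grads[k].ravel()
                for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                    orig = flat[i]
                    flat[i] = orig + eps
                    lp = loss_fn()
                    flat[i] = orig - eps
                    lm = loss_fn()
                    flat[i] = orig
                    numeric = (lp - lm) / (2 * eps)
                    # absolute floor guards analytically-zero gradients
                    denom = max(abs(numeric), abs(dflat[i]), 1e-4)
                    assert abs(numeric - dflat[i]) / denom < 1e-5


class TestPositionalEncoding:
    def _paired_models(self, pe):
        # kernel_size=1 keeps convolution permutation-equivariant, so any
        # order sensitivity comes from the positional encoding alone
        cfg = ModelConfig(input_len=6, input_dim=4, conv_filters=2, n_heads=2,
                          kernel_size=1, dropout_rate=0.0,
                          positional_encoding=pe, seed=4)
        return build_model(cfg)

    def test_disabled_pe_is_permutation_invariant_under_mean_pooling(self, rng):
        m = self._paired_models(pe=False)
        x = rng.normal(size=(1, 6, 4))
        perm = rng.permutation(6)
        np.testing.assert_allclose(m.forward(x), m.forward(x[:, perm]), atol=1e-10)

    def test_enabled_pe_breaks_the_invariance(self, rng):
        m = self._paired_models(pe=True)
        x = rng.normal(size=(1, 6, 4))
        perm = np.array([5, 4, 3, 2, 1, 0])
        assert np.abs(m.forward(x) - m.forward(x[:, perm])).max() > 1e-6


def _toy_problem(rng, n=120, sep=2.0):
    """Linearly separable toy encodings: class mean shifted by ``sep``."""
    y = rng.integers(0, 2, n)
    X = rng.normal(size=(n, 5, 4)) + sep * y[:, None, None]
    return X, y


class TestTraining:
    def test_same_seed_gives_identical_trajectories(self, rng):
        X, y = _toy_problem(rng)
        Xv, yv = _toy_problem(rng, 40)
        tc = TrainConfig(batch_size=16, max_epochs=3, seed=11)
        histories = []
        for _ in range(2):
            m = build_model(ModelConfig(**TINY, seed=11))
            _, hist = train(m, (X, y), (Xv, yv), tc)
            histories.append(hist)
        assert histories[0]["train_loss"] == histories[1]["train_loss"]
        assert histories[0]["val_loss"] == histories[1]["val_loss"]

    def test_single_class_training_set_rejected(self, rng):
        X, y = _toy_problem(rng)
        m = build_model(ModelConfig(**TINY, seed=0))
        with pytest.raises(ValidationError):
            train(m, (X, np.ones_like(y)), (X, y), TrainConfig(max_epochs=1))

    def test_learns_separable_toy_problem(self, rng):
        X, y = _toy_problem(rng, 200)
        Xv, yv = _toy_problem(rng, 80)
        m = build_model(ModelConfig(**TINY, seed=5))
        _, hist = train(m, (X, y), (Xv, yv),
                        TrainConfig(batch_size=16, max_epochs=15, seed=5))
        assert hist["val_acc"][-1] >= 0.9

    def test_history_records_all_curves(self, rng):
        X, y = _toy_problem(rng)
        m = build_model(ModelConfig(**TINY, seed=0))
        _, hist = train(m, (X, y), (X, y), TrainConfig(max_epochs=2, seed=0))
        for key in ("epoch", "train_loss", "val_loss", "train_acc", "val_acc"):
            assert len(hist[key]) == len(hist["epoch"])


class TestPredict:
    def _trained(self, rng):
        X, y = _toy_problem(rng)
        m = build_model(ModelConfig(**TINY, seed=6))
        train(m, (X, y), (X, y), TrainConfig(max_epochs=2, seed=6))
        return m, X

    def test_probabilities_in_unit_interval(self, rng):
        m, X = self._trained(rng)
        probs, calls = predict(m, X)
        assert ((probs >= 0) & (probs <= 1)).all()
        assert set(np.unique(calls)) <= {0, 1}

    def test_batch_equals_concatenated_singles(self, rng):
        m, X = self._trained(rng)
        batch = m.predict_proba(X[:6])
        singles = np.concatenate([m.predict_proba(X[i : i + 1]) for i in range(6)])
        np.testing.assert_allclose(batch, singles, atol=1e-12)

    def test_probability_at_threshold_calls_positive(self, rng):
        m, X = self._trained(rng)
        probs = m.predict_proba(X[:1])
        t = float(probs[0])
        if 0.0 < t < 1.0:
            _, calls = predict(m, X[:1], threshold=t)
            assert calls[0] == 1

    def test_save_load_round_trip_preserves_predictions(self, rng, tmp_path):
        m, X = self._trained(rng)
        m.save(tmp_path / "model")
        back = MethylationClassifier.load(tmp_path / "model")
        np.testing.assert_allclose(back.predict_proba(X), m.predict_proba(X),
                                   atol=1e-12)
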