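"""Temporal classifier: tokenization, predictions, capacity, attention map."""

import numpy as np
import pytest

from painfusion.estimators import TemporalPainClassifier
from painfusion.temporal import (TemporalConfig, TemporalNet,
                                 temporal_attention_map, tokenize_embedding)
from tests.conftest import TINY_TEMPORAL


class TestTokenize:
    def test_default_session_embedding_gives_138_tokens(self):
        tokens, _, pad = tokenize_embedding(np.zeros(13800), 100)
        assert tokens.shape == (138, 100) and pad == 0

    def test_short_embedding(self):
        tokens, _, pad = tokenize_embedding(np.zeros(200), 100)
        assert tokens.shape == (2, 100) and pad == 0

    def test_padding_logged_when_not_divisible(self):
        tokens, padded, pad = tokenize_embedding(np.zeros(250), 100)
        assert tokens.shape == (3, 100) and pad == 50

    def test_token_is_exact_slice(self, rng):
        e = rng.normal(size=1000)
        tokens, _, _ = tokenize_embedding(e, 100)
        for i in range(10):
            assert np.array_equal(tokens[i], e[i * 100:(i + 1) * 100])


class TestForward:
    @pytest.mark.parametrize("n_classes", [2, 5])
    def test_logits_length_matches_task(self, n_classes, rng):
        cfg = TemporalConfig(n_classes=n_classes, d_token=50,
                             **TINY_TEMPORAL)
        net = TemporalNet(cfg, seed=0)
        pred = net.predict(rng.normal(size=400))
        assert pred.logits.shape == (n_classes,)
        assert pred.probabilities.sum() == pytest.approx(1.0, abs=1e-6)
        assert pred.label == int(np.argmax(pred.logits))

    def test_eval_determinism(self, rng):
        net = TemporalNet(TemporalConfig(d_token=50, **TINY_TEMPORAL), seed=0)
        e = rng.normal(size=(2, 400))
        net.eval()
        assert np.array_equal(net.forward(e).data, net.forward(e).data)

    def test_default_parameter_budget(self):
        assert TemporalNet(seed=0).n_parameters() == 1629266

    def test_attention_rows_stochastic(self, rng):
        net = TemporalNet(TemporalConfig(d_token=50, **TINY_TEMPORAL), seed=0)
        net.eval()
        net.forward(rng.normal(size=(1, 400)))
        for attn in [net.cross.attn] + [b.attn for b in net.self_attn]:
            assert np.allclose(attn.last_weights.sum(axis=-1), 1.0, atol=1e-5)


class TestAttentionMap:
    def test_width_proportional_to_token_count_and_bounds(self, rng):
        net = TemporalNet(TemporalConfig(d_token=50, **TINY_TEMPORAL), seed=0)
        for t in (4, 8):
            amap = temporal_attention_map(rng.normal(size=t * 50), net,
                                          height=16, width_per_token=6)
            assert amap.shape == (16, 6 * t)
            assert amap.min() >= 0.0 and amap.max() <= 1.0

    def test_constant_head_weights_give_constant_map(self, rng):
        net = TemporalNet(TemporalConfig(d_token=50, **TINY_TEMPORAL), seed=0)
        net.head.weight.data[:] = 0.5
        amap = temporal_attention_map(rng.normal(size=400), net)
        assert np.allclose(amap, amap.flat[0])


class TestCapacity:
    def test_overfits_40_separable_embeddings_within_200_epochs(self, rng):
        """Toy capacity check: separable classes reach training accuracy 1."""
        n, N = 40, 400
        y = np.array([0] * 20 + [1] * 20)
        X = rng.normal(size=(n, N)) + y[:, None] * 1.5
        est = TemporalPainClassifier(d_token=50, epochs=200, lr=1e-3,
                                     warmup_epochs=20, random_state=0,
                                     **TINY_TEMPORAL)
        est.fit(X, y)
        assert (est.predict(X) == y).mean() == 1.0

    def test_loss_curve_non_increasing_on_moving_average(self, rng):
        n, N = 40, 400
        y = np.array([0] * 20 + [1] * 20)
        X = rng.normal(size=(n, N)) + y[:, None] * 1.5
        est = TemporalPainClassifier(d_token=50, epochs=120, lr=1e-3,
                                     warmup_epochs=10, random_state=0,
                                     **TINY_TEMPORAL)
        est.fit(X, y)
        curve = np.array(est.loss_curve_)
        kernel = np.ones(20) / 20
        smooth = np.convolve(curve, kernel, mode="valid")
        assert np.all(np.diff(smooth) <= 1e-3)


class TestSklearnContract:
    def test_get_set_params_round_trip(self):
        est = TemporalPainClassifier(epochs=7)
        params = est.get_params()
        assert params["epochs"] == 7
        est.set_params(epochs=9)
        assert est.get_params()["epochs"] == 9

    def test_fitted_attributes_and_proba(self, rng):
        y = np.array(["NP"] * 10 + ["P4"] * 10)
        X = rng.normal(size=(20, 200)) + (y == "P4")[:, None] * 2.0
        est = TemporalPainClassifier(d_token=50, epochs=30, lr=1e-3,
                                     warmup_epochs=5, random_state=0,
                                     **TINY_TEMPORAL)
        est.fit(X, y)
        assert list(est.classes_) == ["NP", "P4"]
        assert est.n_features_in_ == 200
        proba = est.predict_proba(X)
        assert proba.shape == (20, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert set(est.predict(X)) <= {"NP", "P4"}

    def test_predict_before_fit_raises(self, rng):
        from sklearn.exceptions import NotFittedError
        with pytest.raises(NotFittedError):
            TemporalPainClassifier().predict(rng.normal(size=(2, 10)))

    def test_single_class_rejected(self, rng):
        est = TemporalPainClassifier(epochs=2, **TINY_TEMPORAL)
        with pytest.raises(ValueError):
            est.fit(rng.normal(size=(5, 100)), np.zeros(5))
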