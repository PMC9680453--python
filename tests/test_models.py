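"""Sequence models: gradients, masking, capacity, training protocol."""

import numpy as np
import pytest

from saxlevel.features import FeatureSequence
from saxlevel.models import (
    CnnHeadClassifier,
    CnnRnnClassifier,
    HeadConfig,
    RNNConfig,
    TrainingConfig,
    TrainingHistory,
    build_variant,
    predict_stack,
    select_epoch,
    train,
)
from saxlevel.nn import masked_softmax_xent

B, T, D, H, K = 3, 6, 4, 5, 5


def _batch(seed=0, n_valid=(4, 6, 3)):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(B, T, D))
    mask = np.zeros((B, T), bool)
    for i, n in enumerate(n_valid):
        mask[i, :n] = True
    y = rng.integers(0, K, size=(B, T))
    return X, mask, y


def _tiny_rnn(variant, seed=0):
    cfg = RNNConfig.from_variant(variant, hidden_units=H, time_steps=T)
    return CnnRnnClassifier(D, cfg, HeadConfig(hidden_units=7, dropout_rate=0.0), seed=seed)


ALL_RNN = ["2-lstm", "bi-lstm", "2-gru", "bi-gru"]


class TestGradients:
    @pytest.mark.parametrize("variant", ALL_RNN)
    def test_backprop_matches_central_differences(self, variant):
        """Manual BPTT gradients agree with numerical differentiation."""
        model = _tiny_rnn(variant, seed=3)
        X, mask, y = _batch(1)

        def loss():
            logits = model._forward(X, mask, train=False, rng=None)
            l, _, _ = masked_softmax_xent(
                logits.reshape(B * T, -1), y.reshape(B * T), mask.reshape(B * T))
            return l

        for p in model.params:
            p.grad[...] = 0.0
        model.loss_grad(X, y, mask, rng=np.random.default_rng(0))
        eps = 1e-6
        for p in model.params:
            flat = p.value.reshape(-1)
            idx = np.linspace(0, flat.size - 1, min(20, flat.size)).astype(int)
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss()
                flat[i] = orig - eps
                lm = loss()
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - p.grad.reshape(-1)[i]) < 1e-5 * max(1.0, abs(num))


class TestProbabilityContracts:
    @pytest.mark.parametrize("variant", ALL_RNN)
    def test_rows_sum_to_one(self, variant):
        model = _tiny_rnn(variant)
        X, mask, _ = _batch()
        probs = model.predict_proba(X, mask)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-6)

    def test_cnn_head_rows_sum_to_one(self):
        model = CnnHeadClassifier(D, HeadConfig(hidden_units=7), seed=0)
        probs = model.predict_proba(np.random.default_rng(0).normal(size=(10, D)))
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-6)

    def test_inference_has_no_dropout(self):
        model = CnnHeadClassifier(D, HeadConfig(hidden_units=7, dropout_rate=0.5), seed=0)
        X = np.random.default_rng(1).normal(size=(4, D))
        assert np.array_equal(model.predict_proba(X), model.predict_proba(X))


class TestMaskInvariance:
    @pytest.mark.parametrize("variant", ALL_RNN)
    def test_padded_rows_are_inert(self, variant):
        """Arbitrary garbage in padded feature rows changes neither the
        valid-step predictions nor the loss."""
        model = _tiny_rnn(variant, seed=5)
        X, mask, y = _batch(2)
        X2 = X.copy()
        X2[~mask] = 1e3 * np.random.default_rng(9).normal(size=X2[~mask].shape)
        p1 = model.predict_proba(X, mask)
        p2 = model.predict_proba(X2, mask)
        assert np.max(np.abs(p1[mask] - p2[mask])) < 1e-6
        l1, a1 = model.evaluate(X, y, mask)
        l2, a2 = model.evaluate(X2, y, mask)
        assert abs(l1 - l2) < 1e-6 and a1 == a2

    @pytest.mark.parametrize("variant", ALL_RNN)
    def test_padded_rows_do_not_gradient(self, variant):
        model = _tiny_rnn(variant, seed=5)
        X, mask, y = _batch(2)
        model.loss_grad(X, y, mask, rng=np.random.default_rng(0))
        g1 = [p.grad.copy() for p in model.params]
        for p in model.params:
            p.grad[...] = 0.0
        X2 = X.copy()
        X2[~mask] = 77.0
        model.loss_grad(X2, y, mask, rng=np.random.default_rng(0))
        for a, p in zip(g1, model.params):
            assert np.max(np.abs(a - p.grad)) < 1e-6


class TestDirectionality:
    def test_bidirectional_sees_the_future_unidirectional_cannot(self):
        """Flipping a late slice's features changes an early prediction for
        the bidirectional encoder but not for the stacked unidirectional one."""
        X, mask, _ = _batch(4, n_valid=(6, 6, 6))
        X2 = X.copy()
        X2[:, 5] += 5.0
        uni = _tiny_rnn("2-lstm", seed=1)
        bi = _tiny_rnn("bi-lstm", seed=1)
        d_uni = np.abs(uni.predict_proba(X, mask)[:, 0] - uni.predict_proba(X2, mask)[:, 0])
        d_bi = np.abs(bi.predict_proba(X, mask)[:, 0] - bi.predict_proba(X2, mask)[:, 0])
        assert np.max(d_uni) == 0.0
        assert np.max(d_bi) > 1e-8


class TestCapacity:
    def test_head_parameter_count_closed_form(self):
        model = CnnHeadClassifier(1024, HeadConfig(), seed=0)
        assert model.param_count() == 1024 * 256 + 256 + 256 * 5 + 5

    @pytest.mark.parametrize("cell,gates", [("lstm", 4), ("gru", 3)])
    def test_rnn_parameter_count_closed_form(self, cell, gates):
        d, h = 64, 128
        model = build_variant(f"2-{cell}", d)
        rnn = gates * (d * h + h * h + h) + gates * (h * h + h * h + h)
        head = h * 256 + 256 + 256 * 5 + 5
        assert model.param_count() == rnn + head


class TestTraining:
    def _data(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, T, D))
        mask = np.ones((n, T), bool)
        # learnable rule: label depends on the sign pattern of feature 0
        y = (X[:, :, 0] > 0).astype(np.int64) * 2 + 1
        return X, mask, y

    def test_loss_decreases_on_learnable_task(self):
        model = _tiny_rnn("2-gru", seed=0)
        data = self._data(24)
        _, hist = train(model, data, self._data(8, seed=1),
                        TrainingConfig(epochs=5, batch_size=4, seed=0))
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_history_length_matches_epochs(self):
        model = _tiny_rnn("2-lstm", seed=0)
        _, hist = train(model, self._data(8), self._data(4, seed=1),
                        TrainingConfig(epochs=1, batch_size=4, seed=0))
        assert len(hist) == 1
        assert all(np.isfinite(hist.val_loss))

    def test_training_is_deterministic_under_seed(self):
        runs = []
        for _ in range(2):
            model = _tiny_rnn("bi-gru", seed=2)
            _, hist = train(model, self._data(12), self._data(6, seed=1),
                            TrainingConfig(epochs=3, batch_size=4, seed=7))
            runs.append((hist.val_loss, model.get_weights()))
        assert runs[0][0] == runs[1][0]
        for a, b in zip(runs[0][1], runs[1][1]):
            assert np.array_equal(a, b)

    def test_empty_dataset_rejected(self):
        model = _tiny_rnn("2-lstm")
        with pytest.raises(ValueError, match="non-empty"):
            train(model, (np.empty((0, T, D)), np.empty((0, T), int),
                          np.empty((0, T), bool)),
                  self._data(4), TrainingConfig(epochs=1))

    def test_best_snapshot_tracks_validation_minimum(self):
        model = _tiny_rnn("2-gru", seed=1)
        snaps, hist = train(model, self._data(16), self._data(8, seed=3),
                            TrainingConfig(epochs=4, batch_size=4, seed=0))
        assert snaps.best_epoch == int(np.argmin(hist.val_loss))


class TestSelectEpoch:
    def _hist(self, losses):
        h = TrainingHistory()
        h.val_loss = list(losses)
        h.train_loss = [0.0] * len(losses)
        h.train_acc = [0.0] * len(losses)
        h.val_acc = [0.0] * len(losses)
        return h

    def test_argmin(self):
        assert select_epoch(self._hist([0.9, 0.5, 0.7])) == 1

    def test_tie_breaks_earliest(self):
        assert select_epoch(self._hist([0.5, 0.5])) == 0

    def test_monotone_decreasing_selects_last(self):
        assert select_epoch(self._hist([0.9, 0.8, 0.7, 0.6])) == 3

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            select_epoch(self._hist([]))


class TestPredictStack:
    def _sequence(self, n_valid=4):
        rng = np.random.default_rng(0)
        matrix = np.zeros((T, D))
        matrix[:n_valid] = rng.normal(size=(n_valid, D))
        mask = np.zeros(T, bool)
        mask[:n_valid] = True
        labels = np.full(T, -1)
        labels[:n_valid] = 1
        return FeatureSequence(matrix=matrix, mask=mask, label_sequence=labels)

    def test_one_label_per_valid_step(self):
        model = _tiny_rnn("bi-lstm", seed=0)
        labels, probs = predict_stack(model, self._sequence(4))
        assert len(labels) == 4
        assert probs.shape == (T, 5)

    def test_argmax_semantics_and_tie_break(self):
        from saxlevel.curation import SliceLabel

        row = np.array([0.1, 0.1, 0.6, 0.1, 0.1])
        assert SliceLabel(int(row.argmax())) is SliceLabel.MID
        tie = np.array([0.3, 0.3, 0.2, 0.1, 0.1])
        assert int(tie.argmax()) == 0  # lowest ordinal wins

    def test_incompatible_model_rejected(self):
        with pytest.raises(TypeError):
            predict_stack(object(), self._sequence())
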