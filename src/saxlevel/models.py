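"""Classifier heads over frozen features: CNN-alone and cascaded CNN-RNN.

Five model variants are supported, all trained on frozen backbone
features:

* ``cnn`` — per-image dense head (256 ReLU units, dropout 0.5, softmax
  over the five levels);
* ``2-lstm`` / ``2-gru`` — two stacked unidirectional recurrent layers of
  128 units feeding the same dense head at every time step (many-to-many);
* ``bi-lstm`` / ``bi-gru`` — one bidirectional recurrent layer with 128
  units per direction, then the dense head per step.

Training uses mini-batch Adam with categorical cross-entropy averaged
over valid (unpadded) steps, for a fixed number of epochs; the deployment
epoch is the argmin of the validation-loss curve (earliest on ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .curation import N_CLASSES, SliceLabel
from .features import PAD_LABEL, T_MAX, FeatureSequence, FeatureVector
from .nn import Adam, Bidirectional, GRULayer, Head, LSTMLayer, masked_softmax_xent, softmax

__all__ = [
    "VARIANTS",
    "HeadConfig",
    "RNNConfig",
    "TrainingConfig",
    "TrainingHistory",
    "ModelSnapshots",
    "CnnHeadClassifier",
    "CnnRnnClassifier",
    "build_cnn_head",
    "build_cnn_rnn",
    "build_variant",
    "sequences_to_arrays",
    "train",
    "select_epoch",
    "predict_stack",
]

VARIANTS = ("cnn", "2-lstm", "bi-lstm", "2-gru", "bi-gru")


@dataclass(frozen=True)
class HeadConfig:
    hidden_units: int = 256
    dropout_rate: float = 0.5
    n_classes: int = N_CLASSES

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_classes != N_CLASSES:
            raise ValueError(f"n_classes must be {N_CLASSES}")


@dataclass(frozen=True)
class RNNConfig:
    cell: str  # "lstm" | "gru"
    arrangement: str  # "two-layer" | "bidirectional"
    hidden_units: int = 128  # per direction / per layer
    time_steps: int = T_MAX

    def __post_init__(self) -> None:
        if self.cell not in ("lstm", "gru"):
            raise ValueError(f"unknown cell {self.cell!r}")
        if self.arrangement not in ("two-layer", "bidirectional"):
            raise ValueError(f"unknown arrangement {self.arrangement!r}")

    @classmethod
    def from_variant(cls, variant: str, hidden_units: int = 128, time_steps: int = T_MAX) -> "RNNConfig":
        table = {
            "2-lstm": ("lstm", "two-layer"),
            "bi-lstm": ("lstm", "bidirectional"),
            "2-gru": ("gru", "two-layer"),
            "bi-gru": ("gru", "bidirectional"),
        }
        if variant not in table:
            raise ValueError(f"unknown RNN variant {variant!r}; known: {sorted(table)}")
        cell, arrangement = table[variant]
        return cls(cell=cell, arrangement=arrangement, hidden_units=hidden_units, time_steps=time_steps)


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 50
    batch_size: int = 2  # per-sequence batches; CNN-alone conventionally uses 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.val_loss)


@dataclass
class ModelSnapshots:
    """Best-validation-loss and final weights from one training run."""

    best_weights: list[np.ndarray]
    final_weights: list[np.ndarray]
    best_epoch: int


class CnnHeadClassifier:
    """Per-image classifier on frozen features (the CNN-alone model)."""

    def __init__(self, feature_dim: int, head: HeadConfig = HeadConfig(), seed: int = 0):
        if feature_dim < 1:
            raise ValueError("feature_dim must be >= 1")
        self.feature_dim = feature_dim
        self.head_config = head
        rng = np.random.default_rng(seed)
        self.head = Head(feature_dim, head.hidden_units, head.dropout_rate, head.n_classes, rng)

    @property
    def params(self):
        return self.head.params

    def param_count(self) -> int:
        return sum(p.size for p in self.params)

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p.value[...] = w

    def _check(self, X: np.ndarray) -> None:
        if X.ndim != 2 or X.shape[1] != self.feature_dim:
            raise ValueError(f"expected (N, {self.feature_dim}) features, got {X.shape}")

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        self._check(X)
        return softmax(self.head.forward(X, train=False))

    def loss_grad(self, X: np.ndarray, y: np.ndarray, mask=None, *,
                  rng: np.random.Generator) -> float:
        self._check(X)
        logits = self.head.forward(X, train=True, rng=rng)
        loss, dlogits, _ = masked_softmax_xent(logits, y, mask)
        self.head.backward(dlogits)
        return loss

    def evaluate(self, X: np.ndarray, y: np.ndarray, mask=None) -> tuple[float, float]:
        logits = self.head.forward(X, train=False)
        loss, _, probs = masked_softmax_xent(logits, y, mask)
        pred = probs.argmax(axis=-1)
        sel = np.ones(len(y), dtype=bool) if mask is None else mask
        acc = float((pred[sel] == y[sel]).mean())
        return loss, acc


class CnnRnnClassifier:
    """Many-to-many sequence classifier: recurrent encoder + shared head.

    Maps a padded (B, T, D) feature batch to (B, T, 5) per-step class
    probabilities; masked steps emit nothing to the loss and their content
    cannot influence valid steps (mask carry in the recurrent layers).
    """

    def __init__(self, feature_dim: int, rnn: RNNConfig,
                 head: HeadConfig = HeadConfig(), seed: int = 0):
        if feature_dim < 1:
            raise ValueError("feature_dim must be >= 1")
        self.feature_dim = feature_dim
        self.rnn_config = rnn
        self.head_config = head
        rng = np.random.default_rng(seed)
        cell = LSTMLayer if rnn.cell == "lstm" else GRULayer
        if rnn.arrangement == "two-layer":
            self.encoder = [cell(feature_dim, rnn.hidden_units, rng),
                            cell(rnn.hidden_units, rnn.hidden_units, rng)]
            out_dim = rnn.hidden_units
        else:
            self.encoder = [Bidirectional(cell(feature_dim, rnn.hidden_units, rng),
                                          cell(feature_dim, rnn.hidden_units, rng))]
            out_dim = 2 * rnn.hidden_units
        self.head = Head(out_dim, head.hidden_units, head.dropout_rate, head.n_classes, rng)

    @property
    def params(self):
        out = []
        for layer in self.encoder:
            out.extend(layer.params)
        return out + self.head.params

    def param_count(self) -> int:
        return sum(p.size for p in self.params)

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p.value[...] = w

    def _check(self, X: np.ndarray, mask: np.ndarray) -> None:
        T = self.rnn_config.time_steps
        if X.ndim != 3 or X.shape[1] != T or X.shape[2] != self.feature_dim:
            raise ValueError(
                f"expected (B, {T}, {self.feature_dim}) features, got {X.shape}"
            )
        if mask.shape != X.shape[:2]:
            raise ValueError("mask shape must match (B, T)")

    def _forward(self, X: np.ndarray, mask: np.ndarray, train: bool,
                 rng: np.random.Generator | None) -> np.ndarray:
        h = X
        for layer in self.encoder:
            h = layer.forward(h, mask)
        B, T, D = h.shape
        logits = self.head.forward(h.reshape(B * T, D), train=train, rng=rng)
        return logits.reshape(B, T, -1)

    def predict_proba(self, X: np.ndarray, mask: np.ndarray) -> np.ndarray:
        self._check(X, mask)
        return softmax(self._forward(X, mask, train=False, rng=None))

    def loss_grad(self, X: np.ndarray, y: np.ndarray, mask: np.ndarray, *,
                  rng: np.random.Generator) -> float:
        self._check(X, mask)
        B, T = mask.shape
        logits = self._forward(X, mask, train=True, rng=rng)
        loss, dlogits, _ = masked_softmax_xent(
            logits.reshape(B * T, -1), y.reshape(B * T), mask.reshape(B * T)
        )
        dh = self.head.backward(dlogits)
        dh = dh.reshape(B, T, -1)
        for layer in reversed(self.encoder):
            dh = layer.backward(dh)
        return loss

    def evaluate(self, X: np.ndarray, y: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
        self._check(X, mask)
        B, T = mask.shape
        logits = self._forward(X, mask, train=False, rng=None)
        loss, _, probs = masked_softmax_xent(
            logits.reshape(B * T, -1), y.reshape(B * T), mask.reshape(B * T)
        )
        pred = probs.argmax(axis=-1)
        flat_mask = mask.reshape(B * T)
        acc = float((pred[flat_mask] == y.reshape(B * T)[flat_mask]).mean())
        return loss, acc


def build_cnn_head(feature_dim: int, head: HeadConfig = HeadConfig(), seed: int = 0) -> CnnHeadClassifier:
    return CnnHeadClassifier(feature_dim, head, seed)


def build_cnn_rnn(feature_dim: int, rnn: RNNConfig, head: HeadConfig = HeadConfig(),
                  seed: int = 0) -> CnnRnnClassifier:
    return CnnRnnClassifier(feature_dim, rnn, head, seed)


def build_variant(variant: str, feature_dim: int, head: HeadConfig = HeadConfig(),
                  seed: int = 0, hidden_units: int = 128):
    if variant == "cnn":
        return build_cnn_head(feature_dim, head, seed)
    return build_cnn_rnn(feature_dim, RNNConfig.from_variant(variant, hidden_units), head, seed)


def sequences_to_arrays(
    sequences: Sequence[FeatureSequence],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack FeatureSequences into (X, mask, y) batch arrays."""
    if not sequences:
        raise ValueError("empty sequence list")
    X = np.stack([s.matrix for s in sequences])
    mask = np.stack([s.mask for s in sequences])
    y = np.stack([s.label_sequence for s in sequences])
    # the cross-entropy indexes labels at valid steps only; make padding safe
    y = np.where(y == PAD_LABEL, 0, y)
    return X, mask, y


def train(model, train_data, val_data, config: TrainingConfig) -> tuple[ModelSnapshots, TrainingHistory]:
    """Mini-batch Adam training for a fixed number of epochs.

    ``train_data``/``val_data`` are ``(X, y)`` for the per-image model or
    ``(X, mask, y)`` for sequence models.  Records per-epoch training loss
    (mean over batches, dropout active) and validation loss/accuracy
    (dropout off), and snapshots the best-validation-loss weights so the
    deployment epoch can be chosen from the curve afterwards.
    Deterministic for a fixed config seed.
    """

    def unpack(data):
        if len(data) == 2:
            X, y = data
            return X, y, None
        X, mask, y = data
        return X, y, mask

    Xtr, ytr, mtr = unpack(train_data)
    Xva, yva, mva = unpack(val_data)
    if len(Xtr) == 0 or len(Xva) == 0:
        raise ValueError("training and validation sets must be non-empty")

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params, lr=config.learning_rate)
    history = TrainingHistory()
    best_loss = np.inf
    best_weights = model.get_weights()
    best_epoch = 0
    n = len(Xtr)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            opt.zero_grad()
            loss = model.loss_grad(
                Xtr[idx], ytr[idx], mtr[idx] if mtr is not None else None, rng=rng
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss ({loss}) at epoch {epoch}; aborting"
                )
            opt.step()
            batch_losses.append(loss)
        tr_loss_eval, tr_acc = model.evaluate(Xtr, ytr, mtr)
        va_loss, va_acc = model.evaluate(Xva, yva, mva)
        if not np.isfinite(va_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        history.train_loss.append(float(np.mean(batch_losses)))
        history.val_loss.append(va_loss)
        history.train_acc.append(tr_acc)
        history.val_acc.append(va_acc)
        if va_loss < best_loss:
            best_loss = va_loss
            best_weights = model.get_weights()
            best_epoch = epoch
    return (
        ModelSnapshots(best_weights=best_weights, final_weights=model.get_weights(),
                       best_epoch=best_epoch),
        history,
    )


def select_epoch(history: TrainingHistory) -> int:
    """Deployment epoch: argmin of validation loss, earliest on ties."""
    if len(history) == 0:
        raise ValueError("empty training history")
    return int(np.argmin(history.val_loss))


def predict_stack(model, sequence: FeatureSequence) -> tuple[list[SliceLabel], np.ndarray]:
    """Per-slice predictions for one stack.

    Returns the predicted labels for the N valid steps (argmax per row;
    ties resolve to the lower ordinal) and the full T x 5 probability
    matrix.
    """
    if isinstance(model, CnnRnnClassifier):
        probs = model.predict_proba(sequence.matrix[None], sequence.mask[None])[0]
    elif isinstance(model, CnnHeadClassifier):
        probs = model.predict_proba(sequence.matrix)
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    labels = [SliceLabel(int(probs[t].argmax())) for t in np.flatnonzero(sequence.mask)]
    return labels, probs
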