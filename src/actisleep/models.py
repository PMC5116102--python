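"""Sleep-quality classifiers: six architectures behind one sklearn-style estimator.

:class:`SleepQualityClassifier` predicts the good/poor sleep-quality label of
the upcoming night from the raw awake-time activity vector. Architectures:

========  ====================================================  ================================
name      model                                                 stated optimum
========  ====================================================  ================================
lr        logistic regression (no hidden layer)                 batch 5, dropout 0.5
mlp       one ReLU hidden layer, fully connected                batch 20, dropout 0.1, hidden 15
cnn       1-d convolution + max-pooling                         batch 5, dropout 0.0, 25 filters
                                                                of length 5, pooling length 4
rnn       simple Elman recurrent network                        batch 5, dropout 0.1, hidden 75
lstm      long short-term memory recurrent network              batch 5, dropout 0.5, hidden 100
tb_lstm   LSTM over time-batched (merged-minute) windows        batch 5, dropout 0.5, hidden 100
========  ====================================================  ================================

Training minimizes cross-entropy with RMSprop (max 50 epochs) and stops early
when validation accuracy drops, restoring the previous epoch's parameters.
The positive class is good-quality sleep; ``predict_proba`` exposes the
model's confidence in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import _nn
from .dataset import time_batch
from .scoring import GOOD, POOR

__all__ = [
    "ARCHITECTURES",
    "ModelSpec",
    "TrainConfig",
    "SleepQualityClassifier",
    "build_model",
    "train",
    "predict",
    "parameter_count",
]

# per-architecture optima: (hidden_size, mini_batch_size, dropout)
ARCH_DEFAULTS: dict[str, dict] = {
    "lr": {"hidden_size": 0, "mini_batch_size": 5, "dropout": 0.5},
    "mlp": {"hidden_size": 15, "mini_batch_size": 20, "dropout": 0.1},
    "cnn": {"hidden_size": 0, "mini_batch_size": 5, "dropout": 0.0},
    "rnn": {"hidden_size": 75, "mini_batch_size": 5, "dropout": 0.1},
    "lstm": {"hidden_size": 100, "mini_batch_size": 5, "dropout": 0.5},
    "tb_lstm": {"hidden_size": 100, "mini_batch_size": 5, "dropout": 0.5},
}
ARCHITECTURES = tuple(ARCH_DEFAULTS)


@dataclass(frozen=True)
class ModelSpec:
    """Architecture choice plus its structural hyperparameters."""

    architecture: str = "lr"
    hidden_size: int | None = None
    conv_filters: int = 25
    filter_length: int = 5
    pool_length: int = 4
    time_batch_window: int = 15

    def __post_init__(self) -> None:
        if self.architecture not in ARCH_DEFAULTS:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.hidden_size is not None and self.hidden_size < 0:
            raise ValueError("hidden_size must be >= 0")

    @property
    def resolved_hidden_size(self) -> int:
        if self.hidden_size is None:
            return ARCH_DEFAULTS[self.architecture]["hidden_size"]
        return self.hidden_size


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters; unset fields fall back to the architecture optimum."""

    mini_batch_size: int | None = None
    dropout: float | None = None
    learning_rate: float = 0.001
    max_epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dropout is not None and not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


def _build_network(spec: ModelSpec, input_length: int, dropout: float) -> _nn._Network:
    arch = spec.architecture
    hidden = spec.resolved_hidden_size
    if arch == "lr":
        return _nn.LogisticNet(input_length, dropout=dropout)
    if arch == "mlp":
        if hidden == 0:
            return _nn.MLPNet(input_length, hidden_size=0, dropout=dropout)
        return _nn.MLPNet(input_length, hidden_size=hidden, dropout=dropout)
    if arch == "cnn":
        return _nn.ConvNet(
            input_length,
            n_filters=spec.conv_filters,
            filter_length=spec.filter_length,
            pool_length=spec.pool_length,
            dropout=dropout,
        )
    if arch == "rnn":
        return _nn.ElmanNet(1, hidden_size=hidden, dropout=dropout)
    if arch == "lstm":
        return _nn.LSTMNet(1, hidden_size=hidden, dropout=dropout)
    if arch == "tb_lstm":
        return _nn.LSTMNet(spec.time_batch_window, hidden_size=hidden, dropout=dropout)
    raise AssertionError(arch)


def parameter_count(spec: ModelSpec, input_length: int) -> int:
    """Number of trainable parameters — a pure function of spec and input shape."""
    net = _build_network(spec, input_length, dropout=0.0)
    params = net.init_params(np.random.default_rng(0))
    return sum(v.size for v in params.values())


class SleepQualityClassifier(ClassifierMixin, BaseEstimator):
    """Binary good/poor sleep-quality classifier over awake-time activity.

    Parameters
    ----------
    architecture : {'lr', 'mlp', 'cnn', 'rnn', 'lstm', 'tb_lstm'}
        Which of the six models to build.
    hidden_size, mini_batch_size, dropout : optional
        Override the architecture's stated optimum (see module docstring).
    conv_filters, filter_length, pool_length : int
        CNN topology (defaults 25 / 5 / 4).
    time_batch_window : int
        Minutes merged per step for ``tb_lstm`` (default 15).
    learning_rate : float
        RMSprop learning rate (default 0.001).
    max_epochs : int
        Upper bound on training epochs (default 50; early stopping may halt
        sooner).
    fixed_length : int
        Input length for the fixed-input models (lr/mlp/cnn): shorter awake
        vectors are left-padded with zeros, longer ones keep their most
        recent ``fixed_length`` minutes. Recurrent models consume variable
        length directly with masking.
    validation_fraction : float
        Fraction carved from the training data for early stopping when no
        explicit validation set is passed to :meth:`fit`.
    random_state : int
        Seed for weight init, shuffling and dropout; identical seeds give
        identical fits.

    Attributes
    ----------
    classes_ : ndarray
        The two class labels (positive class = good sleep).
    params_ : dict of ndarray
        Trained weights.
    training_log_ : list of dict
        Per-epoch train loss and validation accuracy.
    n_parameters_ : int
        Trainable parameter count.
    """

    def __init__(
        self,
        architecture: str = "lr",
        hidden_size: int | None = None,
        conv_filters: int = 25,
        filter_length: int = 5,
        pool_length: int = 4,
        time_batch_window: int = 15,
        mini_batch_size: int | None = None,
        dropout: float | None = None,
        learning_rate: float = 0.001,
        max_epochs: int = 50,
        fixed_length: int = 960,
        validation_fraction: float = 0.15,
        random_state: int = 0,
    ):
        self.architecture = architecture
        self.hidden_size = hidden_size
        self.conv_filters = conv_filters
        self.filter_length = filter_length
        self.pool_length = pool_length
        self.time_batch_window = time_batch_window
        self.mini_batch_size = mini_batch_size
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.fixed_length = fixed_length
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------ #

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            architecture=self.architecture,
            hidden_size=self.hidden_size,
            conv_filters=self.conv_filters,
            filter_length=self.filter_length,
            pool_length=self.pool_length,
            time_batch_window=self.time_batch_window,
        )

    def _resolved(self, name: str):
        value = getattr(self, name)
        return ARCH_DEFAULTS[self.architecture][name] if value is None else value

    @staticmethod
    def _as_sequences(X) -> list[np.ndarray]:
        if isinstance(X, np.ndarray) and X.ndim == 2:
            return [np.asarray(row, dtype=float) for row in X]
        seqs = [np.asarray(x, dtype=float).ravel() for x in X]
        if not seqs or any(len(s) == 0 for s in seqs):
            raise ValueError("X must contain non-empty activity vectors")
        return seqs

    def _prepare_batch(self, seqs: list[np.ndarray]):
        """Shape sequences for the architecture and standardize the counts.

        Standardization ((x - mean) / std of the training counts) is applied
        after padding, so a padded position carries the same value as a
        zero-count minute.
        """
        arch = self.architecture
        c, s_ = self.center_, self.scale_
        if arch in ("lr", "mlp", "cnn"):
            L = self.fixed_length
            X = np.zeros((len(seqs), L))
            for i, s in enumerate(seqs):
                tail = s[-L:]
                X[i, L - len(tail) :] = tail
            return (X - c) / s_
        if arch in ("rnn", "lstm"):
            T = max(len(s) for s in seqs)
            X = np.zeros((len(seqs), T, 1))
            mask = np.zeros((len(seqs), T), dtype=bool)
            for i, s in enumerate(seqs):
                X[i, T - len(s) :, 0] = s
                mask[i, T - len(s) :] = True
            return (X - c) / s_, mask
        # tb_lstm: merge consecutive minutes into window vectors per step
        w = self.time_batch_window
        batched = [time_batch(s, w) for s in seqs]
        T = max(len(b) for b in batched)
        X = np.zeros((len(seqs), T, w))
        mask = np.zeros((len(seqs), T), dtype=bool)
        for i, b in enumerate(batched):
            X[i, T - len(b) :] = b
            mask[i, T - len(b) :] = True
        return (X - c) / s_, mask

    def _encode_labels(self, y) -> np.ndarray:
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("need exactly two classes in y")
        if set(classes.tolist()) == {GOOD, POOR}:
            self.classes_ = np.array([POOR, GOOD])
        else:
            self.classes_ = classes
        return (y == self.classes_[1]).astype(float)

    # ------------------------------------------------------------------ #

    def fit(self, X, y, validation_data=None):
        """Train on awake-activity vectors ``X`` (2-d array or list of 1-d arrays).

        ``validation_data=(X_val, y_val)`` supplies the early-stopping set;
        otherwise ``validation_fraction`` of the training data is held out
        (stratified, seed-controlled).
        """
        spec = self._spec()
        seqs = self._as_sequences(X)
        y_bin = self._encode_labels(y)
        if len(seqs) != len(y_bin):
            raise ValueError("X and y length mismatch")
        rng = np.random.default_rng(self.random_state)

        if validation_data is not None:
            val_seqs = self._as_sequences(validation_data[0])
            y_val = (np.asarray(validation_data[1]) == self.classes_[1]).astype(float)
        else:
            idx_val: list[int] = []
            for cls in (0.0, 1.0):
                members = np.flatnonzero(y_bin == cls)
                rng.shuffle(members)
                n_val = max(1, round(self.validation_fraction * len(members)))
                idx_val.extend(members[:n_val])
            val_mask = np.zeros(len(seqs), dtype=bool)
            val_mask[idx_val] = True
            val_seqs = [s for s, m in zip(seqs, val_mask) if m]
            y_val = y_bin[val_mask]
            seqs = [s for s, m in zip(seqs, val_mask) if not m]
            y_bin = y_bin[~val_mask]

        # one global standardization: O(1)-scale inputs for every architecture
        all_values = np.concatenate(seqs)
        self.center_ = float(np.mean(all_values))
        scale = float(np.std(all_values))
        self.scale_ = scale if scale > 0 else 1.0

        input_length = self.fixed_length
        self.network_ = _build_network(spec, input_length, float(self._resolved("dropout")))
        params = self.network_.init_params(rng)
        self.n_parameters_ = sum(v.size for v in params.values())

        train_batch = self._prepare_batch(seqs)
        val_batch = self._prepare_batch(val_seqs)
        self.params_, self.training_log_ = _nn.train_network(
            self.network_,
            params,
            train_batch,
            y_bin,
            val_batch,
            y_val,
            mini_batch_size=int(self._resolved("mini_batch_size")),
            max_epochs=self.max_epochs,
            learning_rate=self.learning_rate,
            rng=rng,
        )
        self.n_epochs_ = len(self.training_log_)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities ``[P(poor), P(good)]``; deterministic (no dropout)."""
        check_is_fitted(self, "params_")
        seqs = self._as_sequences(X)
        batch = self._prepare_batch(seqs)
        p, _ = self.network_.forward(self.params_, batch, train=False, rng=None)
        return np.column_stack([1.0 - p, p])

    def decision_function(self, X) -> np.ndarray:
        """Confidence in the positive (good-sleep) class, in [0, 1]."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        """Predicted label: good iff confidence ≥ 0.5."""
        p = self.predict_proba(X)[:, 1]
        return self.classes_[(p >= 0.5).astype(int)]

    # ------------------------------------------------------------------ #

    def save(self, path: str | Path) -> None:
        """Save weights plus a JSON sidecar (spec, seed, training log)."""
        path = Path(path)
        np.savez(
            path.with_suffix(".npz"),
            scale=self.scale_,
            center=self.center_,
            **self.params_,
        )
        meta = {
            "spec": asdict(self._spec()),
            "params": self.get_params(),
            "classes": [str(c) for c in self.classes_],
            "n_parameters": int(self.n_parameters_),
            "training_log": self.training_log_,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SleepQualityClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        est = cls(**meta["params"])
        data = np.load(path.with_suffix(".npz"))
        est.scale_ = float(data["scale"])
        est.center_ = float(data["center"])
        est.params_ = {k: data[k] for k in data.files if k not in ("scale", "center")}
        est.classes_ = np.array(meta["classes"])
        est.n_parameters_ = meta["n_parameters"]
        est.training_log_ = meta["training_log"]
        est.n_epochs_ = len(est.training_log_)
        est.network_ = _build_network(
            est._spec(), est.fixed_length, float(est._resolved("dropout"))
        )
        return est


# thin functional wrappers ------------------------------------------------- #


def build_model(spec: ModelSpec, input_length: int, cfg: TrainConfig | None = None) -> SleepQualityClassifier:
    """Construct an untrained classifier from an architecture spec."""
    cfg = cfg or TrainConfig()
    return SleepQualityClassifier(
        architecture=spec.architecture,
        hidden_size=spec.hidden_size,
        conv_filters=spec.conv_filters,
        filter_length=spec.filter_length,
        pool_length=spec.pool_length,
        time_batch_window=spec.time_batch_window,
        mini_batch_size=cfg.mini_batch_size,
        dropout=cfg.dropout,
        learning_rate=cfg.learning_rate,
        max_epochs=cfg.max_epochs,
        fixed_length=input_length,
        random_state=cfg.seed,
    )


def train(model: SleepQualityClassifier, train_set, val_set) -> SleepQualityClassifier:
    """Fit with an explicit validation set; returns the fitted model."""
    X_train, y_train = train_set
    return model.fit(X_train, y_train, validation_data=val_set)


def predict(model: SleepQualityClassifier, X):
    """Labels and confidences for ``X`` as ``(labels, confidences)``."""
    conf = model.predict_proba(X)[:, 1]
    return model.classes_[(conf >= 0.5).astype(int)], conf
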