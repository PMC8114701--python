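"""The two base classifiers as scikit-learn estimators.

:class:`BiLstmClassifier` consumes p-nucleotide token vectors through a
word-embedding + bidirectional LSTM network (64 units, dropout 0.4, sigmoid
output, binary cross-entropy, Adam) — the "sequence as sentence" view.
:class:`CnnClassifier` consumes one-hot 4xN matrices through a two-layer
convolutional network (32 then 64 filters, max-pooling, dropout 0.4, 2-way
softmax, categorical cross-entropy, SGD) — the "sequence as image" view.

Both expose ``predict_cp`` returning the confidence probability Cp that a
sample is a lncRNA (for the CNN this is the lncRNA component of the softmax
pair), and ``predict`` applying the decision threshold Cp >= 0.5.  Unit and
filter counts, dropout, losses, optimizers and activations follow the
reference architecture; embedding dimension, kernel and pool sizes, epochs,
batch size and learning rates are free parameters with desk-scale defaults.

Input ``X`` to ``fit``/``predict`` is a sequence of nucleotide strings or
:class:`~lncfuse.io.Transcript` objects; the estimator owns its encoder and
learns the batch width (token count / column count) from the training set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from lncfuse import nn
from lncfuse.encoders import OneHotSequenceEncoder, PNucleotideEncoder

__all__ = [
    "LstmConfig",
    "CnnConfig",
    "BiLstmClassifier",
    "CnnClassifier",
    "build_lstm",
    "build_cnn",
    "train",
    "predict_cp",
]


@dataclass
class LstmConfig:
    """Configuration of the BiLSTM model (vocab 4**p + 1 incl. padding)."""

    p: int = 3
    vocab_size: int = 65
    embed_dim: int = 64
    lstm_units: int = 64
    dropout: float = 0.4
    loss: str = "binary_crossentropy"
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    clipnorm: float | None = None
    epochs: int = 10
    batch_size: int = 32
    seed: int = 0


@dataclass
class CnnConfig:
    """Configuration of the CNN model."""

    conv_filters: tuple[int, int] = (32, 64)
    kernel_size: int = 8
    pool_size: int = 2
    dropout: float = 0.4
    activation_out: str = "softmax"
    loss: str = "categorical_crossentropy"
    optimizer: str = "sgd"
    learning_rate: float = 0.01
    momentum: float = 0.0
    clipnorm: float | None = None
    epochs: int = 10
    batch_size: int = 32
    seed: int = 0


def build_lstm(cfg: LstmConfig, rng: np.random.Generator | None = None) -> nn.BiLstmNet:
    """Build an untrained BiLSTM network from a config.

    Raises
    ------
    ValueError
        If ``vocab_size`` disagrees with ``4**p + 1`` for the configured p.
    """
    expected = 4**cfg.p + 1
    if cfg.vocab_size != expected:
        raise ValueError(
            f"vocab_size {cfg.vocab_size} != 4**p + 1 = {expected} for p={cfg.p}"
        )
    return nn.BiLstmNet(
        vocab_size=cfg.vocab_size,
        embed_dim=cfg.embed_dim,
        units=cfg.lstm_units,
        dropout=cfg.dropout,
        rng=rng or np.random.default_rng(cfg.seed),
    )


def build_cnn(
    cfg: CnnConfig, n_columns: int, rng: np.random.Generator | None = None
) -> nn.ConvNet:
    """Build an untrained CNN for 4 x ``n_columns`` one-hot inputs."""
    return nn.ConvNet(
        n_columns=n_columns,
        filters=tuple(cfg.conv_filters),
        kernel=cfg.kernel_size,
        pool=cfg.pool_size,
        dropout=cfg.dropout,
        rng=rng or np.random.default_rng(cfg.seed),
    )


def train(net, X_enc, y, cfg, rng: np.random.Generator | None = None) -> list[float]:
    """Train a built network on encoded inputs; returns per-epoch loss."""
    y = np.asarray(y, dtype=float)
    rng = rng or np.random.default_rng(cfg.seed)
    if isinstance(net, nn.BiLstmNet):
        opt = nn.Adam(lr=cfg.learning_rate)
        target = y
    else:
        opt = nn.SGD(lr=cfg.learning_rate, momentum=cfg.momentum)
        target = np.column_stack([1.0 - y, y])  # (mRNA, lncRNA) softmax pair
    return nn.train_network(
        net,
        X_enc,
        target,
        opt,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        rng=rng,
        clipnorm=cfg.clipnorm,
    )


def predict_cp(net, X_enc) -> np.ndarray:
    """Confidence probability Cp (lncRNA) per encoded sample."""
    out = net.predict(X_enc)
    if out.ndim == 2:  # CNN softmax pair (mRNA, lncRNA)
        return out[:, 1]
    return out


class _DeepClassifierBase(BaseEstimator, ClassifierMixin):
    """Shared sklearn plumbing for the two deep classifiers."""

    def _rng(self) -> np.random.Generator:
        seed = self.random_state if self.random_state is not None else 0
        return np.random.default_rng(seed)

    def _check_y(self, y) -> np.ndarray:
        y = np.asarray(y)
        labels = set(np.unique(y).tolist())
        if not labels <= {0, 1}:
            raise ValueError(f"labels must be in {{0, 1}}, got {sorted(labels)}")
        self.classes_ = np.array([0, 1])
        return y.astype(float)

    def predict_proba(self, X) -> np.ndarray:
        cp = self.predict_cp(X)
        return np.column_stack([1.0 - cp, cp])

    def predict(self, X) -> np.ndarray:
        # decision rule: label 1 iff Cp >= 0.5
        return (self.predict_cp(X) >= 0.5).astype(int)


class BiLstmClassifier(_DeepClassifierBase):
    """lncRNA/mRNA classifier: p-nucleotide tokens -> BiLSTM -> sigmoid.

    Parameters
    ----------
    p : int
        Word length of the p-nucleotide encoding (3 by default).
    embed_dim, lstm_units, dropout : network hyperparameters
        Defaults 64 / 64 / 0.4.
    epochs, batch_size, learning_rate : training hyperparameters
        Adam on binary cross-entropy.
    width : int or None
        Padded token-vector length; learned from the training set
        (``floor(max L / p)``) when None.
    random_state : int or None
        Seeds initialisation, shuffling and dropout; training is
        reproducible single-threaded.

    Attributes
    ----------
    encoder_ : PNucleotideEncoder
        Fitted encoder carrying ``width_`` and ``vocab_size_``.
    net_ : lncfuse.nn.BiLstmNet
        The trained network.
    history_ : list of float
        Mean training loss per epoch.
    """

    def __init__(
        self,
        p: int = 3,
        embed_dim: int = 64,
        lstm_units: int = 64,
        dropout: float = 0.4,
        epochs: int = 10,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        clipnorm: float | None = None,
        width: int | None = None,
        random_state: int | None = None,
    ):
        self.p = p
        self.embed_dim = embed_dim
        self.lstm_units = lstm_units
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.clipnorm = clipnorm
        self.width = width
        self.random_state = random_state

    def _config(self) -> LstmConfig:
        return LstmConfig(
            p=self.p,
            vocab_size=4**self.p + 1,
            embed_dim=self.embed_dim,
            lstm_units=self.lstm_units,
            dropout=self.dropout,
            learning_rate=self.learning_rate,
            clipnorm=self.clipnorm,
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=self.random_state if self.random_state is not None else 0,
        )

    def fit(self, X, y):
        y = self._check_y(y)
        rng = self._rng()
        self.encoder_ = PNucleotideEncoder(p=self.p, width=self.width).fit(X)
        tokens = self.encoder_.transform(X)
        cfg = self._config()
        self.net_ = build_lstm(cfg, rng=rng)
        self.history_ = train(self.net_, tokens, y, cfg, rng=rng)
        return self

    def predict_cp(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        return predict_cp(self.net_, self.encoder_.transform(X))


class CnnClassifier(_DeepClassifierBase):
    """lncRNA/mRNA classifier: one-hot 4xN matrix -> CNN -> 2-way softmax.

    Cp is the lncRNA component of the softmax pair; the two components sum
    to one per sample.  See :class:`BiLstmClassifier` for the shared API.
    """

    def __init__(
        self,
        conv_filters: tuple[int, int] = (32, 64),
        kernel_size: int = 8,
        pool_size: int = 2,
        dropout: float = 0.4,
        epochs: int = 10,
        batch_size: int = 32,
        learning_rate: float = 0.01,
        momentum: float = 0.0,
        clipnorm: float | None = None,
        n_columns: int | None = None,
        random_state: int | None = None,
    ):
        self.conv_filters = conv_filters
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.clipnorm = clipnorm
        self.n_columns = n_columns
        self.random_state = random_state

    def _config(self) -> CnnConfig:
        return CnnConfig(
            conv_filters=tuple(self.conv_filters),
            kernel_size=self.kernel_size,
            pool_size=self.pool_size,
            dropout=self.dropout,
            learning_rate=self.learning_rate,
            momentum=self.momentum,
            clipnorm=self.clipnorm,
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=self.random_state if self.random_state is not None else 0,
        )

    def fit(self, X, y):
        y = self._check_y(y)
        rng = self._rng()
        self.encoder_ = OneHotSequenceEncoder(n_columns=self.n_columns).fit(X)
        mats = self.encoder_.transform(X)
        cfg = self._config()
        self.net_ = build_cnn(cfg, n_columns=self.encoder_.n_columns_, rng=rng)
        self.history_ = train(self.net_, mats, y, cfg, rng=rng)
        return self

    def predict_cp(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        return predict_cp(self.net_, self.encoder_.transform(X))


# ---------------------------------------------------------------------------
# model persistence (weights + manifest, so prediction re-encodes identically)


def save_model(est, outdir: str | Path) -> None:
    """Serialize a fitted classifier (weights .npz + JSON manifest)."""
    check_is_fitted(est, "net_")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savez(outdir / "weights.npz", **est.net_.params)
    manifest = {
        "kind": "lstm" if isinstance(est, BiLstmClassifier) else "cnn",
        "params": est.get_params(),
        "history": list(est.history_),
    }
    if isinstance(est, BiLstmClassifier):
        manifest["width"] = int(est.encoder_.width_)
    else:
        manifest["n_columns"] = int(est.encoder_.n_columns_)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_model(modeldir: str | Path):
    """Load a classifier saved by :func:`save_model`."""
    modeldir = Path(modeldir)
    manifest = json.loads((modeldir / "manifest.json").read_text())
    params = dict(np.load(modeldir / "weights.npz"))
    init = dict(manifest["params"])
    if manifest["kind"] == "lstm":
        est = BiLstmClassifier(**{**init, "width": manifest["width"]})
        est.encoder_ = PNucleotideEncoder(p=est.p, width=manifest["width"]).fit(["A" * est.p])
        est.net_ = build_lstm(est._config())
    else:
        init["conv_filters"] = tuple(init["conv_filters"])
        est = CnnClassifier(**{**init, "n_columns": manifest["n_columns"]})
        est.encoder_ = OneHotSequenceEncoder(n_columns=manifest["n_columns"]).fit(["A"])
        est.net_ = build_cnn(est._config(), n_columns=manifest["n_columns"])
    est.net_.params = params
    est.history_ = manifest["history"]
    est.classes_ = np.array([0, 1])
    return est
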