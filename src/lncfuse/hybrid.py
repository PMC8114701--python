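"""Decision-level fusion of the two confidence probabilities.

Each strategy *selects* one of the two confidence probabilities Cp_L
(BiLSTM) and Cp_C (CNN) per sample — never an average — based on
decisiveness ``|2*Cp - 1|`` (distance of the confidence from the 0.5
fence):

* greedy: take the more decisive of the two (ties go to the CNN);
* CNN-dominant: take Cp_C unless the CNN is indecisive
  (``|2*Cp_C - 1| <= 0.5``), in which case fall back to Cp_L;
* LSTM-dominant: the mirror image, with the LSTM as the main model.

The fused Cp maps to a label by the fixed threshold: 1 (lncRNA) iff
Cp >= 0.5.  LSTM-dominant is the default strategy.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.validation import check_is_fitted

from lncfuse.models import BiLstmClassifier, CnnClassifier

__all__ = [
    "fuse_greedy",
    "fuse_cnn_dominant",
    "fuse_lstm_dominant",
    "fuse",
    "to_label",
    "HybridClassifier",
    "STRATEGIES",
]


def _check_cp(cp_l, cp_c):
    cp_l = np.asarray(cp_l, dtype=float)
    cp_c = np.asarray(cp_c, dtype=float)
    for name, v in (("cp_l", cp_l), ("cp_c", cp_c)):
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError(f"{name} outside [0, 1]")
    return cp_l, cp_c


def fuse_greedy(cp_l, cp_c):
    """Greedy selection: the more decisive confidence wins (tie -> CNN)."""
    cp_l, cp_c = _check_cp(cp_l, cp_c)
    out = np.where(np.abs(2 * cp_l - 1) <= np.abs(2 * cp_c - 1), cp_c, cp_l)
    return out if out.ndim else float(out)


def fuse_cnn_dominant(cp_l, cp_c):
    """CNN leads; an indecisive CNN (|2*Cp_C - 1| <= 0.5) defers to the LSTM."""
    cp_l, cp_c = _check_cp(cp_l, cp_c)
    out = np.where(np.abs(2 * cp_c - 1) <= 0.5, cp_l, cp_c)
    return out if out.ndim else float(out)


def fuse_lstm_dominant(cp_l, cp_c):
    """LSTM leads; an indecisive LSTM (|2*Cp_L - 1| <= 0.5) defers to the CNN."""
    cp_l, cp_c = _check_cp(cp_l, cp_c)
    out = np.where(np.abs(2 * cp_l - 1) <= 0.5, cp_c, cp_l)
    return out if out.ndim else float(out)


STRATEGIES = {
    "greedy": fuse_greedy,
    "cnn": fuse_cnn_dominant,
    "lstm": fuse_lstm_dominant,
}


def fuse(cp_l, cp_c, strategy: str = "lstm"):
    """Apply a named hybrid strategy to paired confidence probabilities."""
    try:
        return STRATEGIES[strategy](cp_l, cp_c)
    except KeyError:
        raise ValueError(
            f"unknown strategy {strategy!r}; choose from {sorted(STRATEGIES)}"
        ) from None


def to_label(cp):
    """Decision threshold: label 1 (lncRNA) iff Cp >= 0.5."""
    cp = np.asarray(cp, dtype=float)
    if np.any(cp < 0) or np.any(cp > 1):
        raise ValueError("cp outside [0, 1]")
    out = (cp >= 0.5).astype(int)
    return out if out.ndim else int(out)


class HybridClassifier(BaseEstimator, ClassifierMixin):
    """Hybrid lncRNA/mRNA classifier fusing a BiLSTM and a CNN.

    Fits both base classifiers on the same training sequences and fuses
    their confidence probabilities at decision level.

    Parameters
    ----------
    strategy : {"greedy", "cnn", "lstm"}
        Fusion rule; LSTM-dominant by default.
    lstm, cnn : estimators or None
        Template base classifiers (cloned at fit time); library defaults
        when None.
    random_state : int or None
        Propagated to base classifiers that do not set their own.

    Attributes
    ----------
    lstm_, cnn_ : fitted base classifiers
    """

    def __init__(
        self,
        strategy: str = "lstm",
        lstm: BiLstmClassifier | None = None,
        cnn: CnnClassifier | None = None,
        random_state: int | None = None,
    ):
        self.strategy = strategy
        self.lstm = lstm
        self.cnn = cnn
        self.random_state = random_state

    def fit(self, X, y):
        if self.strategy not in STRATEGIES:
            raise ValueError(
                f"unknown strategy {self.strategy!r}; choose from {sorted(STRATEGIES)}"
            )
        self.lstm_ = clone(self.lstm) if self.lstm is not None else BiLstmClassifier()
        self.cnn_ = clone(self.cnn) if self.cnn is not None else CnnClassifier()
        if self.random_state is not None:
            for est in (self.lstm_, self.cnn_):
                if est.random_state is None:
                    est.set_params(random_state=self.random_state)
        self.lstm_.fit(X, y)
        self.cnn_.fit(X, y)
        self.classes_ = np.array([0, 1])
        return self

    def predict_cp(self, X) -> np.ndarray:
        """Fused confidence probability per sample."""
        check_is_fitted(self, "lstm_")
        return fuse(self.lstm_.predict_cp(X), self.cnn_.predict_cp(X), self.strategy)

    def predict_proba(self, X) -> np.ndarray:
        cp = self.predict_cp(X)
        return np.column_stack([1.0 - cp, cp])

    def predict(self, X) -> np.ndarray:
        return to_label(self.predict_cp(X))
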