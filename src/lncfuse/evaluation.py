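"""Evaluation criteria, ROC/AUC, stratified cross-validation and LSD test.

The positive class is lncRNA (label 1).  From the confusion counts the
five criteria are::

    sensitivity = TP / (TP + FN)          precision = TP / (TP + FP)
    accuracy    = (TP + TN) / total       F1 = 2*TP / (2*TP + FP + FN)
    GM          = sqrt(sensitivity * specificity)

with specificity = TN / (TN + FP); GM is the robust summary on imbalanced
data.  Metrics with a zero denominator are reported as NaN with a warning
(silent zeros would corrupt fold averages).  AUC comes from the ROC curve
(trapezoidal, tie handling equivalent to the normalized Mann-Whitney U).
Method comparison uses Fisher's (unprotected) least-significant-difference
procedure on per-fold accuracies: a one-way ANOVA pooled error variance and
pairwise two-sided t tests on its error degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.base import clone
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class MetricsReport:
    sensitivity: float
    precision: float
    accuracy: float
    f1: float
    gm: float
    auc: float | None = None

    def as_dict(self) -> dict:
        d = {
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "gm": self.gm,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def confusion(labels_true, labels_pred) -> ConfusionCounts:
    """Confusion counts with lncRNA (1) as the positive class."""
    yt = np.asarray(labels_true).astype(int)
    yp = np.asarray(labels_pred).astype(int)
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return float("nan")
    return num / den


def metrics(c: ConfusionCounts) -> MetricsReport:
    """The five confusion-derived criteria (AUC is computed separately)."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    sens = _ratio(c.tp, c.tp + c.fn, "sensitivity")
    prec = _ratio(c.tp, c.tp + c.fp, "precision")
    acc = (c.tp + c.tn) / c.total
    f1 = _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "f1")
    spec = _ratio(c.tn, c.tn + c.fp, "specificity")
    gm = float(np.sqrt(sens * spec)) if not (np.isnan(sens) or np.isnan(spec)) else float("nan")
    return MetricsReport(sensitivity=sens, precision=prec, accuracy=acc, f1=f1, gm=gm)


def roc_auc(cp_values, labels_true) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus ROC curve points (fpr, tpr) from confidence probabilities.

    Raises
    ------
    ValueError
        If only one class is present in the truth labels.
    """
    y = np.asarray(labels_true).astype(int)
    cp = np.asarray(cp_values, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires at least one positive and one negative")
    auc = float(roc_auc_score(y, cp))
    fpr, tpr, _ = roc_curve(y, cp)
    return auc, fpr, tpr


@dataclass
class CvResult:
    """Per-fold and fold-averaged metrics for one method."""

    folds: list[MetricsReport] = field(default_factory=list)

    @property
    def fold_accuracies(self) -> list[float]:
        return [f.accuracy for f in self.folds]

    def mean(self) -> dict:
        keys = ["sensitivity", "precision", "accuracy", "f1", "gm", "auc"]
        out = {}
        for k in keys:
            vals = [getattr(f, k) for f in self.folds]
            if all(v is not None for v in vals):
                out[k] = float(np.nanmean(vals))
        return out


def cross_validate(
    X,
    y,
    estimators: Mapping[str, object],
    k: int = 5,
    seed: int = 0,
) -> dict[str, CvResult]:
    """Stratified k-fold cross-validation of one or more classifiers.

    Each estimator must implement ``fit`` and ``predict_cp`` (confidence
    probability of the positive class); metrics are computed per held-out
    fold at the 0.5 threshold and AUC from the fold's Cp values.
    """
    y = np.asarray(y).astype(int)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"each class needs at least k={k} samples, got counts {counts.tolist()}"
        )
    X = np.asarray(X, dtype=object)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    results = {name: CvResult() for name in estimators}
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        for name, template in estimators.items():
            est = clone(template)
            est.fit(list(X[train_idx]), y[train_idx])
            cp = est.predict_cp(list(X[test_idx]))
            rep = metrics(confusion(y[test_idx], (cp >= 0.5).astype(int)))
            rep.auc = roc_auc(cp, y[test_idx])[0]
            results[name].folds.append(rep)
    return results


def lsd_test(
    accuracy_by_method: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> dict[tuple[str, str], float]:
    """Fisher's LSD: pairwise p-values on per-fold accuracies.

    One-way ANOVA pools the within-method error variance MSE over all
    methods; each pair is compared with ``t = |m_i - m_j| / sqrt(MSE*2/n)``
    on the ANOVA error degrees of freedom, two-sided.  With zero variance
    everywhere, equal means give p = 1 and unequal means p = 0.

    Returns a symmetric dict keyed by method-name pairs; a pair is
    significant at ``alpha`` iff its p-value <= alpha.
    """
    names = list(accuracy_by_method)
    if len(names) < 2:
        raise ValueError("need at least two methods")
    groups = [np.asarray(accuracy_by_method[n], dtype=float) for n in names]
    n = len(groups[0])
    if n < 2 or any(len(g) != n for g in groups):
        raise ValueError("methods must share an equal fold count >= 2")
    df_err = len(groups) * (n - 1)
    sse = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    mse = sse / df_err
    out: dict[tuple[str, str], float] = {}
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            diff = abs(groups[a].mean() - groups[b].mean())
            if mse == 0:
                p = 1.0 if diff == 0 else 0.0
            else:
                t = diff / np.sqrt(mse * 2.0 / n)
                p = float(2.0 * stats.t.sf(t, df_err))
            out[(names[a], names[b])] = p
            out[(names[b], names[a])] = p
    return out
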