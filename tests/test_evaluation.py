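import numpy as np
import pytest
from scipy import stats
from sklearn.base import BaseEstimator

from lncfuse.evaluation import (
    ConfusionCounts,
    confusion,
    cross_validate,
    lsd_test,
    metrics,
    roc_auc,
)


def metrics_oracle(yt, yp):
    """Loop-based counting, no formulas shared with the implementation."""
    tp = fn = fp = tn = 0
    for a, b in zip(yt, yp):
        if a == 1 and b == 1:
            tp += 1
        elif a == 1:
            fn += 1
        elif b == 1:
            fp += 1
        else:
            tn += 1
    sens = tp / (tp + fn) if tp + fn else float("nan")
    prec = tp / (tp + fp) if tp + fp else float("nan")
    acc = (tp + tn) / (tp + fn + fp + tn)
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    gm = (sens * spec) ** 0.5
    return (tp, fn, fp, tn), (sens, prec, acc, f1, gm)


class TestConfusion:
    def test_hand_count(self):
        c = confusion([1, 1, 0, 0], [1, 0, 1, 0])
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)

    def test_perfect(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert c.fn == 0 and c.fp == 0

    def test_inverted(self):
        c = confusion([1, 0], [0, 1])
        assert c.tp == 0 and c.tn == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([1, 0], [1])


class TestMetrics:
    def test_worked_example(self):
        rep = metrics(ConfusionCounts(tp=9, fn=1, fp=2, tn=8))
        assert rep.sensitivity == pytest.approx(0.9)
        assert rep.precision == pytest.approx(9 / 11)
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.f1 == pytest.approx(18 / 21)
        assert rep.gm == pytest.approx(np.sqrt(0.9 * 0.8))

    def test_perfect_prediction_all_ones(self):
        rep = metrics(ConfusionCounts(tp=5, fn=0, fp=0, tn=5))
        assert (rep.sensitivity, rep.precision, rep.accuracy, rep.f1, rep.gm) == (
            1, 1, 1, 1, 1)

    def test_zero_tp_with_fn(self):
        rep = metrics(ConfusionCounts(tp=0, fn=3, fp=0, tn=7))
        assert rep.sensitivity == 0 and rep.gm == 0

    def test_undefined_metric_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="precision"):
            rep = metrics(ConfusionCounts(tp=0, fn=3, fp=0, tn=7))
        assert np.isnan(rep.precision)

    def test_empty_counts_error(self):
        with pytest.raises(ValueError, match="empty"):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_matches_counting_oracle(self, rng):
        for _ in range(1000):
            n = int(rng.integers(4, 40))
            yt = rng.integers(0, 2, size=n)
            yp = rng.integers(0, 2, size=n)
            if yt.sum() in (0, n):
                continue
            counts, vals = metrics_oracle(yt, yp)
            c = confusion(yt, yp)
            assert (c.tp, c.fn, c.fp, c.tn) == counts
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = metrics(c)
            got = (rep.sensitivity, rep.precision, rep.accuracy, rep.f1, rep.gm)
            for g, w in zip(got, vals):
                if np.isnan(w):
                    assert np.isnan(g)
                else:
                    assert g == pytest.approx(w, abs=1e-12)

    def test_f1_equals_harmonic_mean_identity(self, rng):
        for _ in range(100):
            c = ConfusionCounts(*(int(x) for x in rng.integers(1, 50, size=4)))
            rep = metrics(c)
            harm = 2 * rep.precision * rep.sensitivity / (rep.precision + rep.sensitivity)
            assert rep.f1 == pytest.approx(harm)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _, _ = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_constant_scores(self):
        auc, _, _ = roc_auc([0.5] * 10, [1, 0] * 5)
        assert auc == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="positive and one negative"):
            roc_auc([0.5, 0.6], [1, 1])

    def test_matches_mann_whitney_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(6, 60))
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            cp = np.round(rng.random(n), 2)  # coarse grid forces ties
            auc = roc_auc(cp, y)[0]
            u = stats.mannwhitneyu(cp[y == 1], cp[y == 0]).statistic
            want = u / (y.sum() * (n - y.sum()))
            assert auc == pytest.approx(want, abs=1e-12)

    def test_random_scores_near_half(self, rng):
        y = rng.integers(0, 2, size=2000)
        cp = rng.random(2000)
        assert 0.45 <= roc_auc(cp, y)[0] <= 0.55


class GcThreshold(BaseEstimator):
    """Cheap deterministic stand-in classifier for CV machinery tests."""

    def fit(self, X, y):
        return self

    def predict_cp(self, X):
        gc = np.array([(s.count("G") + s.count("C")) / len(s) for s in X])
        return np.clip(gc, 0, 1)


class TestCrossValidate:
    def make_data(self, rng, n=50):
        pos = ["".join(rng.choice(list("ATCG"), size=60, p=[0.15, 0.15, 0.35, 0.35]))
               for _ in range(n)]
        neg = ["".join(rng.choice(list("ATCG"), size=60, p=[0.35, 0.35, 0.15, 0.15]))
               for _ in range(n)]
        return pos + neg, np.array([1] * n + [0] * n)

    def test_fold_sizes(self, rng):
        X, y = self.make_data(rng)
        res = cross_validate(X, y, {"gc": GcThreshold()}, k=5, seed=0)
        assert len(res["gc"].folds) == 5
        # 50+50 samples, stratified: each fold holds out 10+10
        for rep in res["gc"].folds:
            assert rep.accuracy >= 0.8  # strongly separated by construction

    def test_deterministic_folds(self, rng):
        X, y = self.make_data(rng)
        a = cross_validate(X, y, {"gc": GcThreshold()}, k=5, seed=3)
        b = cross_validate(X, y, {"gc": GcThreshold()}, k=5, seed=3)
        assert a["gc"].fold_accuracies == b["gc"].fold_accuracies

    def test_too_few_samples_per_class_errors(self):
        with pytest.raises(ValueError, match="at least k"):
            cross_validate(["AT"] * 6, [1, 1, 1, 0, 0, 0], {"gc": GcThreshold()}, k=5)

    def test_mean_report_keys(self, rng):
        X, y = self.make_data(rng)
        res = cross_validate(X, y, {"gc": GcThreshold()}, k=3, seed=0)
        m = res["gc"].mean()
        assert set(m) == {"sensitivity", "precision", "accuracy", "f1", "gm", "auc"}


class TestLsd:
    def test_identical_methods_p_one(self):
        accs = [0.9, 0.92, 0.91, 0.9, 0.93]
        p = lsd_test({"a": accs, "b": accs})
        assert p[("a", "b")] == 1.0

    def test_separated_methods_significant(self):
        a = [0.95, 0.96, 0.95, 0.96, 0.95]
        b = [0.70, 0.71, 0.70, 0.69, 0.70]
        p = lsd_test({"a": a, "b": b})
        # closed-form oracle: pooled MSE and t on 2(n-1) df
        n = 5
        mse = (np.var(a, ddof=1) + np.var(b, ddof=1)) / 2
        t = abs(np.mean(a) - np.mean(b)) / np.sqrt(mse * 2 / n)
        want = 2 * stats.t.sf(t, 2 * (n - 1))
        assert p[("a", "b")] == pytest.approx(want)
        assert p[("a", "b")] <= 0.001

    def test_zero_variance_equal_means(self):
        p = lsd_test({"a": [0.9, 0.9], "b": [0.9, 0.9]})
        assert p[("a", "b")] == 1.0

    def test_three_methods_symmetric_pairs(self):
        p = lsd_test({"a": [0.9, 0.91], "b": [0.8, 0.81], "c": [0.7, 0.71]})
        pairs = {k for k in p if k[0] < k[1]}
        assert len(pairs) == 3
        for a, b in pairs:
            assert p[(a, b)] == p[(b, a)]

    def test_single_method_errors(self):
        with pytest.raises(ValueError, match="two methods"):
            lsd_test({"a": [0.9, 0.9]})
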