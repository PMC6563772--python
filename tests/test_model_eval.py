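"""Metric correctness, CV protocol leakage checks, and the significance gate."""

import numpy as np
import pytest

from plasmasec.model_eval import (
    ConfusionCounts,
    CVConfig,
    LogisticPipeline,
    compare_significance,
    confusion,
    fit_logistic,
    metrics,
    predict_proba,
    repeated_undersample_cv,
    roc_auc,
)


class TestLogistic:
    def test_separable_1d(self):
        x = np.linspace(-2, 2, 40).reshape(-1, 1)
        y = (x.ravel() > 0).astype(int)
        model = fit_logistic(x, y, l2=1.0)
        assert model.weights[0] > 0
        acc = np.mean((predict_proba(model, x) > 0.5) == y)
        assert acc == 1.0

    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        n = 5000
        x = rng.normal(size=(n, 1))
        p = 1 / (1 + np.exp(-(2.0 * x.ravel() - 1.0)))
        y = (rng.random(n) < p).astype(int)
        model = fit_logistic(x, y, l2=1e-4)
        assert model.weights[0] == pytest.approx(2.0, abs=0.15)
        assert model.intercept == pytest.approx(-1.0, abs=0.15)

    def test_constant_feature_gets_zero_weight(self):
        rng = np.random.default_rng(1)
        x = np.column_stack([rng.normal(size=200), np.full(200, 3.0)])
        y = (x[:, 0] > 0).astype(int)
        model = fit_logistic(x, y, l2=1.0)
        assert abs(model.weights[1]) < 1e-4

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.zeros((5, 1)), np.ones(5, dtype=int))

    def test_proba_closed_forms(self):
        model = fit_logistic(np.array([[-1.0], [1.0]] * 10),
                             np.array([0, 1] * 10))
        model.weights = np.array([1.0])
        model.intercept = 0.0
        assert predict_proba(model, np.array([[0.0]]))[0] == pytest.approx(0.5)
        assert predict_proba(model, np.array([[np.log(3)]]))[0] == pytest.approx(0.75)
        p = predict_proba(model, np.array([[1.3], [-1.3]]))
        assert p[0] + p[1] == pytest.approx(1.0)


class TestConfusionMetrics:
    def test_hand_confusion(self):
        cm = confusion(np.array([1, 1, 0, 0]), np.array([0.9, 0.4, 0.6, 0.1]))
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 1, 1, 1)

    def test_perfect_prediction(self):
        cm = ConfusionCounts(tp=50, tn=50, fp=0, fn=0)
        rep = metrics(cm)
        for name in ("sensitivity", "specificity", "precision", "accuracy", "f1", "mcc"):
            assert getattr(rep, name) == 1.0

    def test_chance_level(self):
        rep = metrics(ConfusionCounts(25, 25, 25, 25))
        assert rep.accuracy == 0.5
        assert rep.mcc == 0.0

    def test_hand_arithmetic(self):
        rep = metrics(ConfusionCounts(tp=40, fn=10, tn=35, fp=15))
        assert rep.mcc == pytest.approx(1250 / np.sqrt(50 * 55 * 50 * 45), abs=1e-9)
        assert rep.mcc == pytest.approx(0.5025, abs=1e-4)
        assert rep.f1 == pytest.approx(0.7619, abs=1e-4)

    def test_zero_denominator_flags(self):
        rep = metrics(ConfusionCounts(tp=0, tn=10, fp=0, fn=0))
        assert rep.sensitivity == 0.0
        assert "sensitivity" in rep.degenerate

    def test_brute_force_agreement(self):
        """metrics() from counts matches recomputation from raw labels."""
        rng = np.random.default_rng(2)
        for _ in range(1000):
            y = rng.integers(0, 2, size=30)
            pred = rng.integers(0, 2, size=30)
            if len(set(y.tolist())) < 2:
                continue
            cm = confusion(y, pred.astype(float), threshold=0.5)
            rep = metrics(cm)
            tp = int(np.sum((y == 1) & (pred == 1)))
            tn = int(np.sum((y == 0) & (pred == 0)))
            fp = int(np.sum((y == 0) & (pred == 1)))
            fn = int(np.sum((y == 1) & (pred == 0)))
            assert (cm.tp, cm.tn, cm.fp, cm.fn) == (tp, tn, fp, fn)
            acc = (tp + tn) / 30
            assert rep.accuracy == pytest.approx(acc)
            den = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
            mcc = (tp * tn - fn * fp) / np.sqrt(den) if den else 0.0
            assert rep.mcc == pytest.approx(mcc)

    def test_mcc_symmetries(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(1, 30, size=4)
            m1 = metrics(ConfusionCounts(tp, tn, fp, fn)).mcc
            m2 = metrics(ConfusionCounts(tn, tp, fn, fp)).mcc  # swap tp<->tn, fp<->fn
            m3 = metrics(ConfusionCounts(fn, fp, tn, tp)).mcc  # label flip
            assert m1 == pytest.approx(m2)
            assert m3 == pytest.approx(-m1)


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc(np.array([0, 0, 1, 1]), np.array([0.1, 0.2, 0.8, 0.9]))
        assert auc == 1.0

    def test_hand_three_quarters(self):
        y = np.array([1, 1, 0, 0])
        s = np.array([0.9, 0.4, 0.5, 0.1])
        _, auc = roc_auc(y, s)
        assert auc == pytest.approx(0.75)

    def test_all_ties_is_half(self):
        _, auc = roc_auc(np.array([0, 1, 0, 1]), np.full(4, 0.3))
        assert auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.ones(4, dtype=int), np.arange(4, dtype=float))

    def test_rank_statistic_equals_trapezoid(self):
        """Mid-rank AUC == trapezoidal area under the stepwise curve,
        independently computed with scikit-learn, on tied score sets."""
        from sklearn.metrics import roc_curve
        rng = np.random.default_rng(4)
        for _ in range(1000):
            n = rng.integers(4, 40)
            y = rng.integers(0, 2, size=n)
            if len(set(y.tolist())) < 2:
                continue
            scores = np.round(rng.random(n), 1)  # force ties
            _, auc = roc_auc(y, scores)
            fpr, tpr, _ = roc_curve(y, scores)
            assert auc == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-12)


class TestRepeatedUndersampleCV:
    def _pools(self, rng, n=120, d=4, effect=2.0):
        pos = rng.normal(effect, 1.0, size=(n, d))
        neg = rng.normal(0.0, 1.0, size=(n, d))
        return pos, neg

    def test_fold_balance(self):
        rng = np.random.default_rng(5)
        pos, neg = self._pools(rng, n=60)
        seen = {}

        class Probe(LogisticPipeline):
            def fit(self, X, y):
                seen.setdefault("sizes", []).append((len(y), int(y.sum())))
                return super().fit(X, y)

        cfg = CVConfig(folds=5, repeats=1, pos_sample=50, neg_sample=50, seed=0)
        repeated_undersample_cv(pos, neg, cfg, {"p": Probe})
        # 5 train splits of 80 samples, 40 per class
        assert all(s == (80, 40) for s in seen["sizes"])

    def test_constant_predictor_chance_auc(self):
        rng = np.random.default_rng(6)
        pos, neg = self._pools(rng, n=80, effect=2.0)

        class Constant(LogisticPipeline):
            def fit(self, X, y):
                return self

            def predict_proba(self, X):
                return np.full(X.shape[0], 0.5)

        cfg = CVConfig(folds=5, repeats=5, pos_sample=60, neg_sample=60, seed=1)
        res = repeated_undersample_cv(pos, neg, cfg, {"c": Constant})["c"]
        assert res.mean["auc"] == pytest.approx(0.5)

    def test_stdev_matches_recomputation(self):
        rng = np.random.default_rng(7)
        pos, neg = self._pools(rng, n=80)
        cfg = CVConfig(folds=4, repeats=6, pos_sample=60, neg_sample=60, seed=2)
        res = repeated_undersample_cv(pos, neg, cfg, {"m": LogisticPipeline})["m"]
        aucs = [r.auc for r in res.per_repeat]
        assert res.std["auc"] == pytest.approx(np.std(aucs, ddof=1))
        assert res.mean["auc"] == pytest.approx(np.mean(aucs))

    def test_pool_too_small_rejected(self):
        cfg = CVConfig(folds=2, repeats=1, pos_sample=50, neg_sample=50, seed=0)
        with pytest.raises(ValueError):
            repeated_undersample_cv(np.zeros((10, 2)), np.zeros((100, 2)), cfg,
                                    {"m": LogisticPipeline})

    def test_no_test_fold_leakage_canary(self):
        """A feature informative only through leakage must not lift AUC.

        Here every feature is pure noise; any AUC above chance would mean
        test-fold data influenced standardization, selection or fitting.
        """
        rng = np.random.default_rng(8)
        pos = rng.normal(size=(80, 10))
        neg = rng.normal(size=(80, 10))

        def selector(X, y):
            # wrapper-style selection run on training data only
            corr = np.abs([np.corrcoef(X[:, j], y)[0, 1] for j in range(X.shape[1])])
            mask = np.zeros(X.shape[1], dtype=bool)
            mask[np.argmax(corr)] = True
            return mask

        cfg = CVConfig(folds=5, repeats=5, pos_sample=60, neg_sample=60, seed=3)
        res = repeated_undersample_cv(
            pos, neg, cfg, {"sel": lambda: LogisticPipeline(selector=selector)})["sel"]
        assert abs(res.mean["auc"] - 0.5) < 0.12


class TestSignificanceGate:
    def test_identical_samples_degenerate(self):
        a = [0.8, 0.82, 0.79, 0.81, 0.8]
        p, test = compare_significance(a, list(a))
        assert p == 1.0
        assert test == "degenerate"

    def test_large_shift_significant(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0.0, 0.01, size=10)
        b = a + 10.0 + rng.normal(0.0, 0.01, size=10)
        p, test = compare_significance(a, b)
        assert p < 1e-3
        assert test in ("paired-t", "wilcoxon")

    def test_gate_picks_wilcoxon_for_heavy_tails(self):
        rng = np.random.default_rng(10)
        # standard Cauchy differences fail Shapiro essentially always
        a = rng.standard_cauchy(50)
        b = np.zeros(50)
        p, test = compare_significance(a, b)
        assert test == "wilcoxon"

    def test_type_i_error_calibrated(self):
        """Null rejection rate at alpha=0.05 stays near 0.05."""
        rng = np.random.default_rng(11)
        rejections = 0
        trials = 1000
        for _ in range(trials):
            a = rng.normal(size=10)
            b = rng.normal(size=10)
            p, _ = compare_significance(a, b)
            rejections += p < 0.05
        assert rejections / trials == pytest.approx(0.05, abs=0.02)
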