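"""Logistic-regression modelling and the binary-classification evaluation protocol.

Covers: L2-penalised logistic regression (via scikit-learn), the
standard confusion-matrix metric suite (sensitivity, specificity,
precision, accuracy, F1, Matthews correlation coefficient), ROC/AUC by
the rank statistic, repeated balanced-undersampling stratified
cross-validation (draw equal-size class samples, k-fold CV, repeat, and
report mean +/- sample standard deviation over repeats), and a
normality-gated paired significance comparison: Shapiro-Wilk on the
paired differences at alpha = 0.05, then a paired t-test when normal
and a Wilcoxon signed-rank test otherwise.

MCC uses the standard square-root form,
``(tp*tn - fn*fp) / sqrt((tp+fn)(tp+fp)(tn+fp)(tn+fn))``.
Zero-denominator metrics are defined as 0 and flagged rather than
raising, so that wrapper-selection fitness evaluation is total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "CVConfig",
    "CVResult",
    "LogisticModel",
    "fit_logistic",
    "predict_proba",
    "confusion",
    "metrics",
    "roc_auc",
    "Standardizer",
    "LogisticPipeline",
    "repeated_undersample_cv",
    "compare_significance",
]

METRIC_NAMES = ("sensitivity", "specificity", "precision", "accuracy", "f1", "mcc", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    f1: float
    mcc: float
    auc: Optional[float] = None
    degenerate: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        out = {name: getattr(self, name) for name in METRIC_NAMES if getattr(self, name) is not None}
        return out


@dataclass
class CVConfig:
    folds: int = 5
    repeats: int = 10
    pos_sample: int = 250
    neg_sample: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class CVResult:
    per_repeat: list[MetricReport]
    mean: dict[str, float]
    std: dict[str, float]

    @classmethod
    def from_reports(cls, reports: Sequence[MetricReport]) -> "CVResult":
        mean, std = {}, {}
        for name in METRIC_NAMES:
            vals = [getattr(r, name) for r in reports]
            if any(v is None for v in vals):
                continue
            arr = np.array(vals, dtype=float)
            mean[name] = float(arr.mean())
            std[name] = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        return cls(per_repeat=list(reports), mean=mean, std=std)


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

@dataclass
class LogisticModel:
    weights: np.ndarray
    intercept: float
    converged: bool = True


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    l2: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> LogisticModel:
    """Fit an L2-penalised logistic regression.

    ``l2`` is the penalty strength (scikit-learn's ``C`` is ``1 / l2``).
    Non-convergence at ``max_iter`` warns but still returns the model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present to fit")
    clf = LogisticRegression(
        penalty="l2", C=1.0 / l2, tol=tol, max_iter=max_iter, solver="lbfgs"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn's own convergence warning
        clf.fit(X, y)
    converged = int(np.max(clf.n_iter_)) < max_iter
    if not converged:
        warnings.warn(f"logistic regression did not converge within {max_iter} iterations")
    return LogisticModel(weights=clf.coef_.ravel().copy(), intercept=float(clf.intercept_[0]),
                         converged=converged)


def predict_proba(model: LogisticModel, X: np.ndarray) -> np.ndarray:
    """Probability of the positive (secretory) class for each row."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.weights.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} != model dimension {model.weights.shape[0]}"
        )
    score = X @ model.weights + model.intercept
    return 1.0 / (1.0 + np.exp(-score))


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def confusion(y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts for predictions ``score > threshold``."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores must have equal length")
    pred = scores > threshold
    pos = y_true == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _safe_div(num: float, den: float, flag: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(flag)
        return 0.0
    return num / den


def metrics(cm: ConfusionCounts) -> MetricReport:
    """Sensitivity, specificity, precision, accuracy, F1 and MCC from counts."""
    if cm.total == 0:
        raise ValueError("cannot compute metrics on an empty confusion table")
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    flags: list[str] = []
    sens = _safe_div(tp, tp + fn, "sensitivity", flags)
    spec = _safe_div(tn, tn + fp, "specificity", flags)
    prec = _safe_div(tp, tp + fp, "precision", flags)
    acc = (tp + tn) / cm.total
    f1 = _safe_div(2 * sens * prec, sens + prec, "f1", flags)
    denom = float(tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    mcc = _safe_div(tp * tn - fn * fp, np.sqrt(denom) if denom > 0 else 0.0, "mcc", flags)
    return MetricReport(sensitivity=sens, specificity=spec, precision=prec,
                        accuracy=acc, f1=f1, mcc=mcc, degenerate=flags)


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points and AUC by the mid-rank statistic.

    AUC equals P(score_pos > score_neg) + 0.5 * P(tie), which is also
    the trapezoidal area under the stepwise ROC curve.  Returns
    ``(points, auc)`` where points has columns (fpr, tpr, threshold).
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for ROC/AUC")
    ranks = stats.rankdata(scores)  # mid-ranks on ties
    auc = (ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    # Stepwise ROC curve at every distinct threshold, descending.
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_y = y_true[order]
    tps = np.cumsum(sorted_y == 1)
    fps = np.cumsum(sorted_y == 0)
    distinct = np.r_[np.nonzero(np.diff(sorted_scores))[0], len(sorted_scores) - 1]
    points = np.column_stack(
        [fps[distinct] / n_neg, tps[distinct] / n_pos, sorted_scores[distinct]]
    )
    points = np.vstack([[0.0, 0.0, np.inf], points])
    return points, float(auc)


# ---------------------------------------------------------------------------
# Pipelines and repeated undersampling CV
# ---------------------------------------------------------------------------

class Standardizer:
    """Per-feature z-scoring with parameters fit on training data only."""

    def __init__(self) -> None:
        self.center: Optional[np.ndarray] = None
        self.scale: Optional[np.ndarray] = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        self.center = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) / self.scale


class LogisticPipeline:
    """Standardize -> (optional column subset / selection) -> logistic fit.

    ``selector`` may be a fixed boolean mask over columns, or a callable
    ``(X, y) -> mask`` run on the training data at fit time (wrapper
    feature selection never sees held-out data).
    """

    def __init__(
        self,
        mask: Optional[np.ndarray] = None,
        selector: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None,
        l2: float = 1.0,
        max_iter: int = 1000,
    ) -> None:
        self.mask = None if mask is None else np.asarray(mask, dtype=bool)
        self.selector = selector
        self.l2 = l2
        self.max_iter = max_iter
        self.model: Optional[LogisticModel] = None
        self.standardizer = Standardizer()
        self.fitted_mask: Optional[np.ndarray] = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LogisticPipeline":
        if self.selector is not None:
            self.fitted_mask = np.asarray(self.selector(X, y), dtype=bool)
        elif self.mask is not None:
            self.fitted_mask = self.mask
        else:
            self.fitted_mask = np.ones(X.shape[1], dtype=bool)
        Xs = X[:, self.fitted_mask]
        self.standardizer.fit(Xs)
        self.model = fit_logistic(self.standardizer.transform(Xs), y,
                                  l2=self.l2, max_iter=self.max_iter)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("pipeline is not fitted")
        Xs = self.standardizer.transform(X[:, self.fitted_mask])
        return predict_proba(self.model, Xs)


def _one_repeat(
    X: np.ndarray,
    y: np.ndarray,
    folds: int,
    pipeline_factory: Callable[[], LogisticPipeline],
    fold_seed: int,
) -> MetricReport:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fold_seed)
    oof = np.empty(len(y))
    for train_idx, test_idx in skf.split(X, y):
        pipe = pipeline_factory()
        pipe.fit(X[train_idx], y[train_idx])
        oof[test_idx] = pipe.predict_proba(X[test_idx])
    report = metrics(confusion(y, oof))
    _, auc = roc_auc(y, oof)
    report.auc = auc
    return report


def repeated_undersample_cv(
    pos_X: np.ndarray,
    neg_X: np.ndarray,
    cfg: CVConfig,
    pipelines: dict[str, Callable[[], LogisticPipeline]],
) -> dict[str, CVResult]:
    """Repeated balanced-undersampling stratified k-fold cross-validation.

    Per repeat: draw ``pos_sample`` positives and ``neg_sample``
    negatives without replacement, run stratified k-fold CV fitting each
    pipeline on train folds only, and score the pooled out-of-fold
    predictions.  All pipelines see identical repeat samples and fold
    splits, so their per-repeat metrics are paired.  Aggregation is
    mean +/- sample standard deviation (ddof=1) over repeats.
    """
    pos_X = np.asarray(pos_X, dtype=float)
    neg_X = np.asarray(neg_X, dtype=float)
    if cfg.pos_sample > pos_X.shape[0] or cfg.neg_sample > neg_X.shape[0]:
        raise ValueError(
            f"class pools ({pos_X.shape[0]} pos, {neg_X.shape[0]} neg) smaller than "
            f"requested samples ({cfg.pos_sample}/{cfg.neg_sample})"
        )
    rng = np.random.default_rng(cfg.seed)
    reports: dict[str, list[MetricReport]] = {name: [] for name in pipelines}
    for _ in range(cfg.repeats):
        pi = rng.choice(pos_X.shape[0], size=cfg.pos_sample, replace=False)
        ni = rng.choice(neg_X.shape[0], size=cfg.neg_sample, replace=False)
        X = np.vstack([pos_X[pi], neg_X[ni]])
        y = np.r_[np.ones(cfg.pos_sample, dtype=int), np.zeros(cfg.neg_sample, dtype=int)]
        fold_seed = int(rng.integers(0, 2**31 - 1))
        for name, factory in pipelines.items():
            reports[name].append(_one_repeat(X, y, cfg.folds, factory, fold_seed))
    return {name: CVResult.from_reports(reps) for name, reps in reports.items()}


# ---------------------------------------------------------------------------
# Significance comparison
# ---------------------------------------------------------------------------

def compare_significance(
    metric_a: Sequence[float],
    metric_b: Sequence[float],
    alpha: float = 0.05,
    paired: bool = True,
) -> tuple[float, str]:
    """Normality-gated two-sided comparison of two metric samples.

    Paired mode (default): Shapiro-Wilk on the paired differences at
    ``alpha``; normal -> paired t-test, otherwise Wilcoxon signed-rank.
    Returns ``(p_value, test_name)``; all-zero differences yield
    ``(1.0, "degenerate")``.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("samples must have equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 paired values")
    if paired:
        d = a - b
        if np.all(d == 0):
            return 1.0, "degenerate"
        if np.all(d == d[0]):
            # Constant non-zero shift: zero variance, the shift is certain.
            return 0.0, "degenerate-constant-shift"
        normal = stats.shapiro(d).pvalue > alpha
        if normal:
            res = stats.ttest_rel(a, b)
            return float(res.pvalue), "paired-t"
        res = stats.wilcoxon(a, b, zero_method="zsplit")
        return float(res.pvalue), "wilcoxon"
    # Unpaired fallback: gate on both samples being normal.
    if np.all(a == a[0]) and np.all(b == b[0]):
        return (1.0, "degenerate") if a[0] == b[0] else (0.0, "degenerate-constant-shift")
    normal = (not np.all(a == a[0]) and stats.shapiro(a).pvalue > alpha) and (
        not np.all(b == b[0]) and stats.shapiro(b).pvalue > alpha
    )
    if normal:
        res = stats.ttest_ind(a, b)
        return float(res.pvalue), "t"
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.pvalue), "mannwhitney"
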