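"""Model selection, evaluation and the reader-comparison statistics.

Two learners are supported: L2 logistic regression and an SVM (linear or
RBF kernel). Hyperparameters are chosen by exhaustive grid search scored
with stratified 2-fold CV AUC on a stratified 80% subset of the training
cases (ties take the first grid point in declared order). Evaluation is
stratified 5-fold CV on the training set: per fold the z-score
normalization and the model are refit on the 4 training folds, scores are
taken on the held-out fold, and the ROC/AUC uses the trapezoidal rule over
all score thresholds; the report carries mean +/- sample SD of the fold
AUCs. The hold-out test applies training normalization statistics to a
disjoint validation set and reports exact-fraction accuracy. SVM scores
are signed decision margins (AUC is rank-based, so no calibration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .features import zscore_apply, zscore_fit

LEARNERS = ("logistic_regression", "svm")


def default_grid(learner: str, n_features: int) -> list[dict]:
    """Declared hyperparameter grids, in tie-break order."""
    cs = (0.01, 0.1, 1.0, 10.0, 100.0)
    if learner == "logistic_regression":
        return [{"C": c} for c in cs]
    if learner == "svm":
        grid = [{"kernel": "linear", "C": c} for c in cs]
        for c in cs:
            for gamma in (1.0 / max(n_features, 1), 0.01, 0.1, 1.0):
                grid.append({"kernel": "rbf", "C": c, "gamma": gamma})
        return grid
    raise ValueError(f"unknown learner {learner!r}; expected one of {LEARNERS}")


def make_model(learner: str, params: dict):
    if learner == "logistic_regression":
        return LogisticRegression(solver="liblinear", max_iter=500, **params)
    if learner == "svm":
        return SVC(**params)
    raise ValueError(f"unknown learner {learner!r}")


def _scores(model, X) -> np.ndarray:
    return model.decision_function(X)


@dataclass
class ModelConfig:
    """Model-selection and evaluation parameters."""

    learner: str = "logistic_regression"
    grid: list[dict] | None = None
    inner_folds: int = 2
    tuning_fraction: float = 0.8
    eval_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learner not in LEARNERS:
            raise ValueError(f"learner must be one of {LEARNERS}")
        if not (0 < self.tuning_fraction < 1):
            raise ValueError("tuning_fraction must be in (0, 1)")
        if self.inner_folds < 2 or self.eval_folds < 2:
            raise ValueError("fold counts must be >= 2")


@dataclass
class EvalReport:
    """Repeated-CV AUC evaluation plus optional hold-out results."""

    fold_aucs: list[float]
    mean_auc: float
    sd_auc: float
    roc_curves: list[dict]
    params: dict
    seed: int
    holdout_accuracy: float | None = None
    holdout_fraction: str | None = None
    holdout_predictions: dict | None = None

    def to_dict(self) -> dict:
        return {
            "fold_aucs": self.fold_aucs,
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "params": self.params,
            "seed": self.seed,
            "holdout_accuracy": self.holdout_accuracy,
            "holdout_fraction": self.holdout_fraction,
            "holdout_predictions": self.holdout_predictions,
        }


def tune(X: pd.DataFrame, y: np.ndarray, config: ModelConfig) -> dict:
    """Grid search with stratified ``inner_folds``-fold CV AUC on a
    stratified ``tuning_fraction`` subset of the training cases.

    Returns the winning hyperparameters; ties keep the earlier grid point.
    """
    y = np.asarray(y)
    if min(np.bincount(y)) < 2 * config.inner_folds:
        raise ValueError("too few cases per class for nested tuning")
    grid = config.grid or default_grid(config.learner, X.shape[1])
    if len(grid) == 1:
        return dict(grid[0])
    idx = np.arange(len(y))
    sub, _ = train_test_split(
        idx, train_size=config.tuning_fraction, stratify=y,
        random_state=config.seed,
    )
    Xs, ys = X.iloc[sub], y[sub]
    skf = StratifiedKFold(n_splits=config.inner_folds, shuffle=True,
                          random_state=config.seed)
    best_params, best_auc = None, -np.inf
    for params in grid:
        aucs = []
        for tr, va in skf.split(Xs, ys):
            model = make_model(config.learner, params).fit(Xs.iloc[tr], ys[tr])
            aucs.append(roc_auc_score(ys[va], _scores(model, Xs.iloc[va])))
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc:  # strict: first grid point wins ties
            best_auc, best_params = mean_auc, dict(params)
    return best_params


def evaluate_cv(
    X: pd.DataFrame, y: np.ndarray, config: ModelConfig, params: dict,
    normalize: bool = True,
) -> EvalReport:
    """Stratified ``eval_folds``-fold CV AUC of a fitted model family.

    Normalization (when requested; pass already-normalized tables with
    ``normalize=False``) is refit on each fold's training portion.
    """
    y = np.asarray(y)
    if len(y) < 2 * config.eval_folds:
        raise ValueError("too few cases for evaluation folds")
    skf = StratifiedKFold(n_splits=config.eval_folds, shuffle=True,
                          random_state=config.seed)
    fold_aucs, curves = [], []
    for tr, va in skf.split(X, y):
        if len(np.unique(y[va])) < 2:
            raise ValueError("a fold contains a single class")
        Xtr, Xva = X.iloc[tr], X.iloc[va]
        if normalize:
            stats = zscore_fit(Xtr)
            Xtr, Xva = zscore_apply(Xtr, stats), zscore_apply(Xva, stats)
        model = make_model(config.learner, params).fit(Xtr, y[tr])
        s = _scores(model, Xva)
        fpr, tpr, _ = roc_curve(y[va], s)
        fold_aucs.append(float(roc_auc_score(y[va], s)))
        curves.append({"fpr": fpr.tolist(), "tpr": tpr.tolist()})
    return EvalReport(
        fold_aucs=fold_aucs,
        mean_auc=float(np.mean(fold_aucs)),
        sd_auc=float(np.std(fold_aucs, ddof=1)),
        roc_curves=curves,
        params=dict(params),
        seed=config.seed,
    )


def test_holdout(
    X_train: pd.DataFrame, y_train: np.ndarray,
    X_val: pd.DataFrame, y_val: np.ndarray,
    config: ModelConfig, params: dict,
) -> tuple[float, Fraction, pd.Series]:
    """Fit on the full training set, predict the disjoint validation set.

    Normalization statistics come from the training rows only. Returns
    (accuracy, exact fraction, per-case predictions). Raises on any
    overlap between training and validation case ids.
    """
    overlap = set(X_train.index) & set(X_val.index)
    if overlap:
        raise ValueError(f"training/validation overlap: {sorted(overlap)[:5]}")
    stats = zscore_fit(X_train)
    model = make_model(config.learner, params).fit(
        zscore_apply(X_train, stats), np.asarray(y_train)
    )
    pred = model.predict(zscore_apply(X_val, stats))
    correct = int((pred == np.asarray(y_val)).sum())
    frac = Fraction(correct, len(y_val))
    return correct / len(y_val), frac, pd.Series(pred, index=X_val.index)


@dataclass
class ReaderComparison:
    """One-sample t-test of reader accuracies against the model accuracy."""

    reader_accuracies: list[float]
    model_accuracy: float
    t_statistic: float
    p_value: float
    shapiro_p: float
    mean: float
    median: float
    ci95: tuple[float, float]
    significant: bool  # at the conventional p < 0.05 level

    def to_dict(self) -> dict:
        return {
            "reader_accuracies": self.reader_accuracies,
            "model_accuracy": self.model_accuracy,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "shapiro_p": self.shapiro_p,
            "mean": self.mean,
            "median": self.median,
            "ci95": list(self.ci95),
            "significant": self.significant,
        }


def compare_readers(
    reader_accuracies: list[float], model_accuracy: float
) -> ReaderComparison:
    """Two-sided one-sample t-test of reader accuracies vs the model.

    Also reports the Shapiro-Wilk normality p-value, the reader median and
    the 95% CI of the reader mean (mean +/- t_{0.975, n-1} * SE).
    """
    acc = np.asarray(reader_accuracies, dtype=np.float64)
    if len(acc) < 3:
        raise ValueError("need at least 3 reader accuracies")
    if acc.std(ddof=1) == 0:
        raise ValueError("degenerate sample: zero variance in reader accuracies")
    t_res = sps.ttest_1samp(acc, popmean=model_accuracy)
    sh = sps.shapiro(acc)
    n = len(acc)
    half = sps.t.ppf(0.975, n - 1) * acc.std(ddof=1) / np.sqrt(n)
    mean = float(acc.mean())
    return ReaderComparison(
        reader_accuracies=acc.tolist(),
        model_accuracy=float(model_accuracy),
        t_statistic=float(t_res.statistic),
        p_value=float(t_res.pvalue),
        shapiro_p=float(sh.pvalue),
        mean=mean,
        median=float(np.median(acc)),
        ci95=(mean - half, mean + half),
        significant=bool(t_res.pvalue < 0.05),
    )
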