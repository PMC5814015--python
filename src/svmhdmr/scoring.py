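"""Linear-kernel SVM classification: continuous scores, cross-validated
misclassification, and repeated random-split generalization estimates.

The decision-function value ("score") of the classifier is the continuous
output that downstream sensitivity analysis regresses on; the hard class
prediction is its sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .datasets import FeatureTable
from .errors import ConfigurationError, DataError

__all__ = [
    "ScoreSet",
    "EvalReport",
    "HoldoutReport",
    "fit_svm",
    "cross_validated_mce",
    "repeated_holdout_eval",
]


@dataclass
class ScoreSet:
    """Continuous classifier scores for the N samples of a table.

    ``predictions`` are the elementwise sign of ``scores`` (0 when a score is
    exactly zero).
    """

    scores: np.ndarray
    mean_score: float
    predictions: np.ndarray
    source: str = ""

    @classmethod
    def from_scores(cls, scores: np.ndarray, source: str = "") -> "ScoreSet":
        scores = np.asarray(scores, dtype=float)
        return cls(
            scores=scores,
            mean_score=float(scores.mean()),
            predictions=np.sign(scores).astype(int),
            source=source,
        )


@dataclass
class EvalReport:
    """Misclassification summary: ``mce = n_misclassified / n_total``."""

    mce: float
    n_misclassified: int
    n_total: int
    per_class_errors: tuple[int, int]  # (negative-class, positive-class)
    folds_or_splits: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "mce": self.mce,
            "n_misclassified": self.n_misclassified,
            "n_total": self.n_total,
            "per_class_errors": list(self.per_class_errors),
            "folds_or_splits": self.folds_or_splits,
            "seed": self.seed,
        }


@dataclass
class HoldoutReport:
    """Mean/std of training and testing MCE over repeated random splits."""

    train_mean: float
    train_std: float
    test_mean: float
    test_std: float
    train_mces: np.ndarray
    test_mces: np.ndarray
    n_repeats: int
    n_train: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "train_mean": self.train_mean,
            "train_std": self.train_std,
            "test_mean": self.test_mean,
            "test_std": self.test_std,
            "n_repeats": self.n_repeats,
            "n_train": self.n_train,
            "seed": self.seed,
        }


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise DataError("degenerate single-class data: cannot fit a classifier")


def _subset_table(table: FeatureTable, feature_subset) -> FeatureTable:
    if feature_subset is None:
        return table
    return table.subset(list(feature_subset))


def _count_errors(labels: np.ndarray, predictions: np.ndarray) -> tuple[int, int]:
    """Per-class misclassification counts; a sign of 0 never matches +-1."""
    wrong = predictions != labels
    return int(np.sum(wrong & (labels == -1))), int(np.sum(wrong & (labels == 1)))


def fit_svm(
    table: FeatureTable,
    feature_subset=None,
    kernel: str = "linear",
    cost: float = 1.0,
    seed: int = 0,
) -> tuple[SVC, ScoreSet]:
    """Fit a linear-kernel SVM and return it with the scores of all samples."""
    if kernel != "linear":
        raise ConfigurationError(f"unsupported classification kernel: {kernel!r}")
    if cost <= 0:
        raise ConfigurationError("SVM cost must be positive")
    sub = _subset_table(table, feature_subset)
    _check_two_classes(sub.labels)
    clf = SVC(kernel="linear", C=cost, random_state=seed)
    clf.fit(sub.values, sub.labels)
    scores = clf.decision_function(sub.values)
    name = ",".join(sub.feature_names)
    return clf, ScoreSet.from_scores(scores, source=f"svm-linear C={cost} [{name}]")


def cross_validated_mce(
    table: FeatureTable,
    feature_subset=None,
    k_folds: int = 10,
    cost: float = 1.0,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold cross-validated misclassification rate.

    Out-of-fold predictions are collected for every sample; the MCE is the
    number of misclassifications divided by N.
    """
    if k_folds < 2:
        raise ConfigurationError("k_folds must be >= 2")
    sub = _subset_table(table, feature_subset)
    _check_two_classes(sub.labels)
    min_class = min(sub.class_counts().values())
    if k_folds > min_class:
        raise ConfigurationError(
            f"k_folds={k_folds} exceeds the minority class size ({min_class})"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    preds = np.zeros(sub.n_samples, dtype=int)
    for train_idx, test_idx in skf.split(sub.values, sub.labels):
        clf = SVC(kernel="linear", C=cost, random_state=seed)
        clf.fit(sub.values[train_idx], sub.labels[train_idx])
        preds[test_idx] = np.sign(clf.decision_function(sub.values[test_idx])).astype(int)
    neg_err, pos_err = _count_errors(sub.labels, preds)
    n_wrong = neg_err + pos_err
    return EvalReport(
        mce=n_wrong / sub.n_samples,
        n_misclassified=n_wrong,
        n_total=sub.n_samples,
        per_class_errors=(neg_err, pos_err),
        folds_or_splits=f"stratified {k_folds}-fold CV",
        seed=seed,
    )


def repeated_holdout_eval(
    table: FeatureTable,
    feature_subset=None,
    n_train: int = 100,
    n_repeats: int = 100,
    inner_folds: int = 10,
    cost: float = 1.0,
    seed: int = 0,
) -> HoldoutReport:
    """Repeated random train/test splits: mean and std of train and test MCE.

    Each repeat draws ``n_train`` samples uniformly at random (no
    stratification) for training; the classifier is built from the training
    split only, its training error is assessed by ``inner_folds``-fold CV on
    the split, and the refit model predicts the held-out samples.
    """
    if n_repeats < 2:
        raise ConfigurationError("n_repeats must be >= 2 (std undefined otherwise)")
    sub = _subset_table(table, feature_subset)
    if n_train >= sub.n_samples:
        raise ConfigurationError("n_train must be smaller than the sample count")
    _check_two_classes(sub.labels)
    rng = np.random.default_rng(seed)
    train_mces = np.empty(n_repeats)
    test_mces = np.empty(n_repeats)
    for r in range(n_repeats):
        perm = rng.permutation(sub.n_samples)
        tr, te = perm[:n_train], perm[n_train:]
        x_tr, y_tr = sub.values[tr], sub.labels[tr]
        x_te, y_te = sub.values[te], sub.labels[te]
        if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
            # vanishingly unlikely for balanced data; redraw deterministically
            perm = rng.permutation(sub.n_samples)
            tr, te = perm[:n_train], perm[n_train:]
            x_tr, y_tr = sub.values[tr], sub.labels[tr]
            x_te, y_te = sub.values[te], sub.labels[te]

        folds = min(inner_folds, int(np.bincount((y_tr + 1) // 2).min()))
        skf = StratifiedKFold(n_splits=max(folds, 2), shuffle=True,
                              random_state=seed + r)
        oof = np.zeros(n_train, dtype=int)
        for tr_i, te_i in skf.split(x_tr, y_tr):
            clf = SVC(kernel="linear", C=cost)
            clf.fit(x_tr[tr_i], y_tr[tr_i])
            oof[te_i] = np.sign(clf.decision_function(x_tr[te_i])).astype(int)
        train_mces[r] = np.mean(oof != y_tr)

        clf = SVC(kernel="linear", C=cost)
        clf.fit(x_tr, y_tr)
        pred = np.sign(clf.decision_function(x_te)).astype(int)
        test_mces[r] = np.mean(pred != y_te)
    return HoldoutReport(
        train_mean=float(train_mces.mean()),
        train_std=float(train_mces.std(ddof=1)),
        test_mean=float(test_mces.mean()),
        test_std=float(test_mces.std(ddof=1)),
        train_mces=train_mces,
        test_mces=test_mces,
        n_repeats=n_repeats,
        n_train=n_train,
        seed=seed,
    )
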