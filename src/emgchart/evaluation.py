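"""Class-separability scoring of features and feature sets.

Two statistical indices (Davies-Bouldin and the Fisher discriminant trace
ratio; lower = more separable, 0 is perfect) and two classifiers (LDA and a
linear one-vs-one SVM) under stratified 10-fold cross-validation, with
Cohen's d for standardized differences between error-rate groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import (GroupKFold, StratifiedKFold,
                                     cross_val_predict)
from sklearn.svm import SVC

__all__ = [
    "davies_bouldin",
    "fisher_lda_index",
    "make_classifier",
    "cv_error",
    "cohens_d",
    "effect_size_label",
    "evaluate_features",
    "EvaluationReport",
]


def _classes(matrix, labels):
    X = np.asarray(matrix, float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels)
    if len(y) != len(X):
        raise ValueError("label count must equal row count")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    return X, y, classes


def davies_bouldin(matrix, labels) -> float:
    """Mean over classes of the worst-case (scatter sum / centroid distance)
    ratio; S_c is the mean Euclidean distance of class rows to their
    centroid."""
    X, y, classes = _classes(matrix, labels)
    cents = np.stack([X[y == c].mean(axis=0) for c in classes])
    scatter = np.array([
        np.mean(np.linalg.norm(X[y == c] - cents[i], axis=1))
        for i, c in enumerate(classes)])
    k = len(classes)
    worst = np.empty(k)
    for i in range(k):
        ratios = []
        for j in range(k):
            if i == j:
                continue
            gap = np.linalg.norm(cents[i] - cents[j])
            if gap == 0:
                if scatter[i] + scatter[j] == 0:
                    continue
                warnings.warn("coincident class centroids: DBI infinite")
                return float("inf")
            ratios.append((scatter[i] + scatter[j]) / gap)
        worst[i] = max(ratios) if ratios else 0.0
    return float(np.mean(worst))


def fisher_lda_index(matrix, labels) -> float:
    """trace(S_w) / trace(S_b) of within- and between-class scatter."""
    X, y, classes = _classes(matrix, labels)
    grand = X.mean(axis=0)
    sw = 0.0
    sb = 0.0
    for c in classes:
        Xc = X[y == c]
        mu = Xc.mean(axis=0)
        sw += float(np.sum((Xc - mu) ** 2))
        sb += len(Xc) * float(np.sum((mu - grand) ** 2))
    if sb == 0:
        warnings.warn("all class means coincide: FLDI infinite")
        return float("inf")
    return sw / sb


def make_classifier(name: str, C: float = 1.0):
    if name == "lda":
        return LinearDiscriminantAnalysis()
    if name == "svm":
        # SVC trains one-vs-one by construction
        return SVC(kernel="linear", C=C)
    raise ValueError(f"unknown classifier {name!r} (use 'lda' or 'svm')")


def cv_error(matrix, labels, classifier: str = "lda", folds: int = 10,
             seed: int = 0, groups=None) -> float:
    """Cross-validated error percentage: incorrect test predictions over all
    test samples x 100.

    Stratified folds by default; passing per-row ``groups`` (e.g. trial ids)
    switches to group-wise folds so windows of one trial never straddle the
    train/test boundary.
    """
    X, y, classes = _classes(matrix, labels)
    counts = pd.Series(y).value_counts()
    if groups is None and counts.min() < folds:
        raise ValueError(
            f"smallest class ({counts.min()} rows) has fewer rows than "
            f"{folds} folds")
    clf = make_classifier(classifier) if isinstance(classifier, str) \
        else classifier
    if groups is not None:
        cv = GroupKFold(n_splits=min(folds, len(np.unique(groups))))
        pred = cross_val_predict(clf, X, y, cv=cv, groups=groups)
    else:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        pred = cross_val_predict(clf, X, y, cv=cv)
    return float(np.mean(pred != y) * 100.0)


def cohens_d(errors_a, errors_b) -> float:
    """Standardized mean difference (pooled sd)."""
    a = np.asarray(errors_a, float)
    b = np.asarray(errors_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    diff = a.mean() - b.mean()
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) if na > 1 else 0.0) + \
                 ((nb - 1) * b.var(ddof=1) if nb > 1 else 0.0)
    dof = max(na + nb - 2, 1)
    sd = np.sqrt(pooled_var / dof)
    if sd == 0:
        if diff == 0:
            return 0.0
        warnings.warn("zero pooled sd with unequal means: d infinite")
        return float(np.sign(diff) * np.inf)
    return float(diff / sd)


def effect_size_label(d: float) -> str:
    """0.2 small / 0.5 medium / >= 0.8 large."""
    m = abs(d)
    if m >= 0.8:
        return "large"
    if m >= 0.5:
        return "medium"
    if m >= 0.2:
        return "small"
    return "negligible"


# ---------------------------------------------------------------------------
# per-feature report

@dataclass
class EvaluationReport:
    """Per-(subject, feature-or-set) separability and CV error table with
    across-subject aggregation."""

    table: pd.DataFrame  # index (subject, feature); cols DBI FLDI LDA SVM

    def aggregate(self) -> pd.DataFrame:
        return self.table.groupby(level="feature").agg(["mean", "std"])

    def ranking(self, criterion: str = "SVM") -> pd.Series:
        """Features sorted best-first (all four criteria are
        lower-is-better)."""
        return self.table.groupby(level="feature")[criterion].mean() \
            .sort_values()

    def write_csv(self, path) -> None:
        self.table.to_csv(path)

    @classmethod
    def read_csv(cls, path) -> "EvaluationReport":
        return cls(pd.read_csv(path, index_col=[0, 1]))


def _feature_matrix(windowed: pd.DataFrame, subject, feature: str):
    """windows x channels matrix for one (subject, feature) with motion
    labels; mirrors 'columns = muscles, rows = analysis segments'."""
    sub = windowed.xs(subject, level="subject")[feature]
    wide = sub.unstack(level="channel")
    labels = wide.index.get_level_values("motion").to_numpy()
    groups = wide.index.get_level_values("trial").to_numpy()
    return wide.to_numpy(), labels, groups


def evaluate_features(windowed: pd.DataFrame,
                      features: list[str] | None = None,
                      classifiers: tuple[str, ...] = ("lda", "svm"),
                      folds: int = 10, seed: int = 0,
                      fold_mode: str = "by-window") -> EvaluationReport:
    """Score every feature for every subject.

    ``windowed`` is a wide per-window feature table (MultiIndex with subject,
    channel, trial, motion, repetition, start).  ``fold_mode`` 'by-trial'
    keeps all windows of a trial in one fold to avoid temporal leakage.
    """
    if features is None:
        features = list(windowed.columns)
    subjects = sorted(windowed.index.get_level_values("subject").unique())
    rows = []
    for subject in subjects:
        for feat in features:
            X, y, trial_groups = _feature_matrix(windowed, subject, feat)
            entry = {"subject": subject, "feature": feat,
                     "DBI": davies_bouldin(X, y),
                     "FLDI": fisher_lda_index(X, y)}
            groups = trial_groups if fold_mode == "by-trial" else None
            for clf in classifiers:
                entry[clf.upper()] = cv_error(X, y, clf, folds=folds,
                                              seed=seed, groups=groups)
            rows.append(entry)
    table = pd.DataFrame(rows).set_index(["subject", "feature"])
    return EvaluationReport(table)
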