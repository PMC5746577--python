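"""Feature-set design: chart-guided representative features, the sequential
forward selection (SFS) baseline, and the train/test + cross-dataset
comparison protocol.

Chart-guided selection follows two guidelines: nodes with low filter values
(tight, strongly correlated sub-groups) contribute a single representative;
nodes with high filter values (looser sub-groups of more independent
features) may contribute several.  Multi-component extraction methods (AR,
CC, TDPSD, ...) are included or excluded atomically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import train_test_split

from .chart import TopologicalChart
from .evaluation import EvaluationReport, cohens_d, cv_error
from .features import FEATURE_FAMILIES, FEATURE_NAMES

__all__ = [
    "SelectionRule",
    "FeatureSet",
    "FEATURE_SET_PRESETS",
    "representative_features",
    "SequentialForwardSelector",
    "sfs",
    "subject_matrix",
    "compare_sets",
]


@dataclass(frozen=True)
class SelectionRule:
    """Quota and ranking policy for chart-guided selection."""

    quota_low: int = 1       # picks per tight (low-filter) group
    quota_high: int = 2      # picks per loose (high-filter) group
    criterion: str = "SVM"   # column of the evaluation report
    split_quantile: float = 0.5  # low/high filter split on group medians

    def __post_init__(self) -> None:
        if self.quota_low < 1 or self.quota_high < 1:
            raise ValueError("quotas must be >= 1")


@dataclass(frozen=True)
class FeatureSet:
    name: str
    members: tuple[str, ...]
    provenance: str = "literature"  # mapper | sfs | literature

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError("feature-set members must be unique")
        unknown = [m for m in self.members if m not in FEATURE_NAMES]
        if unknown:
            raise ValueError(f"unknown feature(s): {unknown}")

    def __len__(self) -> int:
        return len(self.members)


FEATURE_SET_PRESETS: dict[str, FeatureSet] = {
    "TD": FeatureSet("TD", ("MAV", "WL", "ZC", "SSC", "MAVS")),
    "AR_RMS": FeatureSet("AR_RMS", ("AR1", "AR2", "AR3", "AR4", "RMS")),
    "AR_CC_WL": FeatureSet("AR_CC_WL", ("AR1", "AR2", "AR3", "AR4",
                                        "CC1", "CC2", "CC3", "CC4", "WL")),
    # 16-feature chart-guided global set: one-or-few representatives per
    # functional group plus the atomic DAR and TDPSD families
    "mapper_global16": FeatureSet(
        "mapper_global16",
        ("DAMV", "DASDV", "WAMP", "ZC", "SampEn", "MFL",
         "DAR1", "DAR2", "DAR3", "DAR4",
         "TDPSD1", "TDPSD2", "TDPSD3", "TDPSD4", "TDPSD5", "TDPSD6"),
        provenance="mapper"),
    "all": FeatureSet("all", FEATURE_NAMES, provenance="literature"),
}

_FAMILY_OF = {m: fam for fam, members in FEATURE_FAMILIES.items()
              for m in members}


def _units(features: list[str]) -> list[tuple[str, ...]]:
    """Group features into atomic units (families expand to every member)."""
    seen: list[tuple[str, ...]] = []
    for f in features:
        fam = _FAMILY_OF.get(f)
        unit = FEATURE_FAMILIES[fam] if fam else (f,)
        if unit not in seen:
            seen.append(unit)
    return seen


def representative_features(chart: TopologicalChart,
                            report: EvaluationReport,
                            rule: SelectionRule = SelectionRule()
                            ) -> FeatureSet:
    """Pick representatives per annotated functional group.

    Groups whose mean node filter value falls below the ``split_quantile``
    of all node filter values contribute ``quota_low`` units; the rest
    contribute ``quota_high``.  Units are ranked by the report's criterion
    (mean across subjects, lower is better; a family is ranked by its best
    member) and expanded atomically.
    """
    if not chart.nodes:
        return FeatureSet("mapper", (), provenance="mapper")
    if not chart.groups:
        raise ValueError("chart has no group annotations; run "
                         "decompose_chart/annotate_groups first")
    scores = report.table.groupby(level="feature")[rule.criterion].mean()
    missing = [f for n in chart.nodes for f in n.members
               if f not in scores.index]
    if missing:
        raise ValueError(f"report does not cover feature(s) "
                         f"{sorted(set(missing))}")
    split = float(np.quantile([n.mean_filter for n in chart.nodes],
                              rule.split_quantile))
    group_feats: dict[str, list[str]] = {}
    group_filter: dict[str, list[float]] = {}
    for node in chart.nodes:
        label = chart.groups.get(node.id)
        if label is None:
            continue
        feats = group_feats.setdefault(label, [])
        for m in node.members:
            if m not in feats:
                feats.append(m)
        group_filter.setdefault(label, []).append(node.mean_filter)

    chosen: list[str] = []
    for label in sorted(group_feats):
        quota = rule.quota_low if np.mean(group_filter[label]) <= split \
            else rule.quota_high
        units = _units(group_feats[label])
        units.sort(key=lambda u: min(scores[m] for m in u))
        picked = 0
        for unit in units:
            if picked >= quota:
                break
            new = [m for m in unit if m not in chosen]
            if not new:
                continue
            chosen.extend(new)
            picked += 1
    return FeatureSet("mapper", tuple(chosen), provenance="mapper")


# ---------------------------------------------------------------------------
# data shaping

def subject_matrix(windowed: pd.DataFrame, subject,
                   features: tuple[str, ...] | list[str]):
    """(windows x (channels * features) matrix, motion labels) for one
    subject."""
    sub = windowed.xs(subject, level="subject")[list(features)]
    wide = sub.unstack(level="channel")
    labels = wide.index.get_level_values("motion").to_numpy()
    return wide.to_numpy(), labels


# ---------------------------------------------------------------------------
# sequential forward selection

class SequentialForwardSelector(BaseEstimator):
    """Greedy wrapper selection on mean within-subject k-fold CV error.

    ``fit(windowed)`` consumes a per-window wide feature table; at each step
    the candidate whose addition minimizes the mean 10-fold CV error across
    subjects joins the set, until ``k_max`` features are selected.
    Fitted attributes: ``selected_`` (inclusion order), ``step_errors_``.
    """

    def __init__(self, candidates: tuple[str, ...] | None = None,
                 k_max: int = 5, classifier: str = "lda", folds: int = 10,
                 seed: int = 0):
        self.candidates = candidates
        self.k_max = k_max
        self.classifier = classifier
        self.folds = folds
        self.seed = seed

    def fit(self, windowed: pd.DataFrame, y=None):
        candidates = list(self.candidates if self.candidates is not None
                          else windowed.columns)
        if self.k_max > len(candidates):
            raise ValueError("k_max exceeds the number of candidates")
        subjects = sorted(
            windowed.index.get_level_values("subject").unique())
        selected: list[str] = []
        step_errors: list[float] = []
        remaining = list(candidates)
        while len(selected) < self.k_max:
            best_feat, best_err = None, np.inf
            for feat in remaining:
                trial_set = tuple(selected + [feat])
                errs = []
                for s in subjects:
                    X, labels = subject_matrix(windowed, s, trial_set)
                    errs.append(cv_error(X, labels, self.classifier,
                                         folds=self.folds, seed=self.seed))
                err = float(np.mean(errs))
                if err < best_err:
                    best_feat, best_err = feat, err
            selected.append(best_feat)
            remaining.remove(best_feat)
            step_errors.append(best_err)
        self.selected_ = tuple(selected)
        self.step_errors_ = step_errors
        return self


def sfs(candidates, windowed: pd.DataFrame, k_max: int,
        classifier: str = "lda", folds: int = 10, seed: int = 0
        ) -> FeatureSet:
    members = candidates.members if isinstance(candidates, FeatureSet) \
        else tuple(candidates)
    sel = SequentialForwardSelector(members, k_max, classifier,
                                    folds=folds, seed=seed).fit(windowed)
    return FeatureSet("sfs", sel.selected_, provenance="sfs")


# ---------------------------------------------------------------------------
# comparison protocol

def _holdout_error(windowed: pd.DataFrame, members, classifier: str,
                   test_size: float, seed: int) -> list[float]:
    """Per-subject test error after a per-subject 70/30 split stratified by
    motion."""
    from .evaluation import make_classifier
    errors = []
    subjects = sorted(windowed.index.get_level_values("subject").unique())
    for s in subjects:
        X, y = subject_matrix(windowed, s, members)
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, test_size=test_size, stratify=y, random_state=seed)
        clf = make_classifier(classifier)
        clf.fit(Xtr, ytr)
        errors.append(float(np.mean(clf.predict(Xte) != yte) * 100.0))
    return errors


def _cv_errors(windowed: pd.DataFrame, members, classifier: str,
               folds: int, seed: int) -> list[float]:
    errors = []
    subjects = sorted(windowed.index.get_level_values("subject").unique())
    for s in subjects:
        X, y = subject_matrix(windowed, s, members)
        errors.append(cv_error(X, y, classifier, folds=folds, seed=seed))
    return errors


def compare_sets(sets: list[FeatureSet],
                 windowed_tables: dict[str, pd.DataFrame],
                 classifier: str = "svm", test_size: float = 0.3,
                 folds: int = 10, seed: int = 0,
                 include_baseline: bool = True) -> pd.DataFrame:
    """Evaluate feature sets on each dataset's held-out 30% and by k-fold CV
    on every *other* dataset (transfer), with Cohen's d against the
    all-features baseline.

    Returns one row per (set, dataset) with columns ``test_error``,
    ``transfer_error`` (mean over other datasets, NaN if none), their d and
    effect-size labels.
    """
    if not sets or not windowed_tables:
        raise ValueError("need at least one feature set and one dataset")
    sets = list(sets)
    if include_baseline and not any(s.name == "all" for s in sets):
        sets.append(None)  # placeholder: all columns of each table
    baseline_err: dict[str, list[float]] = {}
    for ds, table in windowed_tables.items():
        baseline_err[ds] = _holdout_error(
            table, list(table.columns), classifier, test_size, seed)
    rows = []
    for fset in sets:
        for ds, table in windowed_tables.items():
            members = list(table.columns) if fset is None else \
                list(fset.members)
            name = "all" if fset is None else fset.name
            provenance = "literature" if fset is None else fset.provenance
            missing = [m for m in members if m not in table.columns]
            if missing:
                raise ValueError(f"feature set {name!r} references "
                                 f"unknown feature(s) {missing}")
            test_errs = _holdout_error(table, members, classifier,
                                       test_size, seed)
            transfer = [np.mean(_cv_errors(
                            other_table,
                            list(other_table.columns) if fset is None
                            else members,
                            classifier, folds, seed))
                        for other_ds, other_table in windowed_tables.items()
                        if other_ds != ds]
            d_all = cohens_d(test_errs, baseline_err[ds])
            rows.append({
                "set": name, "provenance": provenance,
                "dataset": ds, "n_features": len(members),
                "test_error": float(np.mean(test_errs)),
                "test_error_sd": float(np.std(test_errs, ddof=1))
                if len(test_errs) > 1 else 0.0,
                "transfer_error": float(np.mean(transfer))
                if transfer else float("nan"),
                "d_vs_all": d_all,
            })
    return pd.DataFrame(rows)
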