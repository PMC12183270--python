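"""Splits, the five classification metrics, fold aggregation and model comparison.

The single stratified 80/10/10 split uses a per-class allocation rule that
reproduces the reference cohort's printed counts (810 patients → 81 test /
80 validation / 649 training; 753 controls → 76 / 75 / 602): per class,
test = ceil(0.1·n); validation = test − 1 if 0.1·n is an integer, else
floor(0.1·n); training takes the remainder. Cross-validation uses stratified
k-fold partitions of the real subjects only; within each iteration the
non-test folds are re-split 8:1 into training/validation per class and then
oversampled, so the held-out fold stays real-only.

Metrics (MDD positive): Acc = (TP+TN)/total, Sen = TP/(TP+FN),
Spe = TN/(TN+FP), Pre = TP/(TP+FP), F1 = 2·Pre·Sen/(Pre+Sen); divisions by
zero are guarded to 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from ._rng import substream, substream_seed
from .cohort import Cohort, SubjectRecord

logger = logging.getLogger(__name__)

METRIC_NAMES = ("acc", "sen", "spe", "pre", "f1")


@dataclass
class SplitPlan:
    train_ids: List[str]
    val_ids: List[str]
    test_ids: List[str]
    rule: str = "test=ceil(f*n); val=test-1 if f*n integral else floor(f*n)"

    def __post_init__(self) -> None:
        parts = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(p) for p in parts)
        if len(set().union(*parts)) != total:
            raise ValueError("train/val/test must be disjoint")


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

    @classmethod
    def from_labels(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass
class MetricReport:
    acc: float
    sen: float
    spe: float
    pre: float
    f1: float
    counts: ConfusionCounts | None = None

    def as_dict(self) -> Dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_NAMES}


@dataclass
class CVSummary:
    """Per-fold reports keyed by model/method name, with mean ± sample SD."""

    fold_reports: Dict[str, List[MetricReport]]
    mean: Dict[str, Dict[str, float]] = field(default_factory=dict)
    sd: Dict[str, Dict[str, float]] = field(default_factory=dict)
    best_fold: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, reports in self.fold_reports.items():
            vals = {m: np.array([getattr(r, m) for r in reports]) for m in METRIC_NAMES}
            self.mean[name] = {m: float(v.mean()) for m, v in vals.items()}
            self.sd[name] = {m: float(v.std(ddof=1)) if len(v) > 1 else 0.0
                             for m, v in vals.items()}
            self.best_fold[name] = int(np.argmax(vals["acc"]))


def _split_counts(n: int, f_test: float, f_val: float) -> Tuple[int, int, int]:
    ft = f_test * n
    test = math.ceil(ft)
    val = test - 1 if abs(ft - round(ft)) < 1e-9 else math.floor(f_val * n)
    train = n - test - val
    if min(train, val, test) < 1:
        raise ValueError(f"class of size {n} leaves an empty partition")
    return train, val, test


def stratified_split(cohort_or_subjects, fractions=(0.8, 0.1, 0.1),
                     seed: int = 0) -> SplitPlan:
    """Random per-class 80/10/10 assignment under the documented count rule."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    subjects = (cohort_or_subjects.subjects
                if isinstance(cohort_or_subjects, Cohort) else list(cohort_or_subjects))
    rng = substream(seed, "split")
    train_ids, val_ids, test_ids = [], [], []
    for label in sorted({s.label for s in subjects}):
        ids = sorted(s.subject_id for s in subjects if s.label == label)
        rng.shuffle(ids)
        n_train, n_val, n_test = _split_counts(len(ids), fractions[2], fractions[1])
        test_ids += ids[:n_test]
        val_ids += ids[n_test:n_test + n_val]
        train_ids += ids[n_test + n_val:]
    return SplitPlan(sorted(train_ids), sorted(val_ids), sorted(test_ids))


def stratified_kfold(cohort_or_subjects, k: int = 10, seed: int = 0,
                     ) -> List[Tuple[List[str], List[str]]]:
    """k disjoint stratified folds over the *real* subjects.

    Returns (train_ids, test_ids) per fold; per-class fold sizes differ by at
    most one.
    """
    subjects = (cohort_or_subjects.real_subjects()
                if isinstance(cohort_or_subjects, Cohort)
                else [s for s in cohort_or_subjects if not s.is_synthetic])
    subjects = sorted(subjects, key=lambda s: s.subject_id)
    y = np.array([s.label for s in subjects])
    for label in np.unique(y):
        if np.sum(y == label) < k:
            raise ValueError(f"class {label} has fewer than {k} subjects")
    ids = np.array([s.subject_id for s in subjects])
    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=substream_seed(seed, "kfold"))
    return [(sorted(ids[tr]), sorted(ids[te])) for tr, te in skf.split(ids, y)]


def train_val_split(subjects: Sequence[SubjectRecord], val_fraction: float = 1.0 / 9.0,
                    seed: int = 0) -> Tuple[List[str], List[str]]:
    """Per-class random train/validation split of a CV iteration's non-test folds."""
    rng = substream(seed, "trainval")
    train_ids, val_ids = [], []
    for label in sorted({s.label for s in subjects}):
        ids = sorted(s.subject_id for s in subjects if s.label == label)
        rng.shuffle(ids)
        n_val = max(1, round(val_fraction * len(ids)))
        val_ids += ids[:n_val]
        train_ids += ids[n_val:]
    return sorted(train_ids), sorted(val_ids)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); returning 0", what)
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    """The five metrics from confusion counts, MDD as the positive class."""
    if counts.total == 0:
        raise ValueError("empty confusion matrix")
    acc = (counts.tp + counts.tn) / counts.total
    sen = _safe_div(counts.tp, counts.tp + counts.fn, "sensitivity")
    spe = _safe_div(counts.tn, counts.tn + counts.fp, "specificity")
    pre = _safe_div(counts.tp, counts.tp + counts.fp, "precision")
    f1 = _safe_div(2 * pre * sen, pre + sen, "F1")
    return MetricReport(acc=acc, sen=sen, spe=spe, pre=pre, f1=f1, counts=counts)


def summarize_cv(fold_reports: Dict[str, List[MetricReport]] | List[MetricReport]) -> CVSummary:
    if isinstance(fold_reports, list):
        fold_reports = {"model": fold_reports}
    for name, reports in fold_reports.items():
        if len(reports) < 2:
            raise ValueError(f"{name}: need >= 2 folds to summarize")
    return CVSummary(fold_reports=dict(fold_reports))


def compare_models(reports_a: Sequence[MetricReport], reports_b: Sequence[MetricReport],
                   equal_var: bool = True, alpha: float = 0.05) -> Dict[str, Dict[str, float]]:
    """Two-sided independent two-sample t-test per metric across folds.

    Zero pooled variance with equal means yields p = 1 by convention.
    Returns {metric: {"t", "p", "significant"}}.
    """
    if len(reports_a) < 2 or len(reports_b) < 2:
        raise ValueError("need >= 2 folds per model")
    out: Dict[str, Dict[str, float]] = {}
    for m in METRIC_NAMES:
        a = np.array([getattr(r, m) for r in reports_a])
        b = np.array([getattr(r, m) for r in reports_b])
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            t, p = 0.0, 1.0
        else:
            res = stats.ttest_ind(a, b, equal_var=equal_var)
            t, p = float(res.statistic), float(res.pvalue)
            if not np.isfinite(p):
                p = 1.0
        out[m] = {"t": t, "p": p, "significant": bool(p < alpha)}
    return out
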