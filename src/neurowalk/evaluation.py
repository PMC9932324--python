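"""Cross-validation harnesses and classification metrics.

The positive class is ASD.  Metrics follow the standard confusion-table
definitions; the F-score is computed both as TP / (TP + (FP + FN) / 2)
and as 2 P R / (P + R) — the two forms are algebraically identical and
the implementation asserts their agreement.  Ratios with a zero
denominator are reported as ``None`` (explicit "undefined"), never NaN.

Two schemes are provided:

* stratified k-fold over the pooled cohort (label-stratified, site-blind);
* leave-one-site-out (LOSO): one fold per acquisition site, training on
  all other sites — the measure of cross-site generalization.

Every fold re-fits the full pipeline (tangent reference, rasterization
bounds, normalization, classifier) on the training subjects only; the
harness collects each fitted statistic's subject audit so tests can
prove the absence of leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class MetricSet:
    accuracy: float | None
    precision: float | None
    recall: float | None
    fscore: float | None


@dataclass
class FoldResult:
    fold_id: str
    n_subjects: int
    n_positive: int
    counts: ConfusionCounts
    metrics: MetricSet


@dataclass
class CVResult:
    scheme: str  # "kfold" | "leave_one_site_out"
    folds: list  # of FoldResult
    mean_metrics: MetricSet = None
    leakage_audit: list = field(default_factory=list)  # (fold_id, stat_name, train_ids, test_ids)

    def mean_accuracy(self) -> float:
        vals = [f.metrics.accuracy for f in self.folds if f.metrics.accuracy is not None]
        return float(np.mean(vals))


def _safe_div(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Accuracy, precision, recall and F-score from confusion counts."""
    precision = _safe_div(c.TP, c.TP + c.FP)
    recall = _safe_div(c.TP, c.TP + c.FN)
    f1_counts = _safe_div(c.TP, c.TP + 0.5 * (c.FP + c.FN))
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1_pr = 2 * precision * recall / (precision + recall)
        assert abs(f1_counts - f1_pr) < 1e-12, "F-score identity violated"
    accuracy = _safe_div(c.TP + c.TN, c.total)
    return MetricSet(accuracy=accuracy, precision=precision, recall=recall, fscore=f1_counts)


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


def _mean_metrics(folds) -> MetricSet:
    def mean_of(attr):
        vals = [getattr(f.metrics, attr) for f in folds]
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    return MetricSet(
        accuracy=mean_of("accuracy"),
        precision=mean_of("precision"),
        recall=mean_of("recall"),
        fscore=mean_of("fscore"),
    )


def _run_fold(pipeline_factory, train_subjects, test_subjects, fold_id) -> tuple:
    pipe = pipeline_factory()
    pipe.fit(train_subjects)
    y_true = np.array([1 if s.label == "ASD" else 0 for s in test_subjects])
    y_pred = pipe.predict(test_subjects)
    counts = confusion_from_predictions(y_true, y_pred)
    fold = FoldResult(
        fold_id=str(fold_id),
        n_subjects=len(test_subjects),
        n_positive=int(y_true.sum()),
        counts=counts,
        metrics=compute_metrics(counts),
    )
    train_ids = {s.subject_id for s in train_subjects}
    test_ids = {s.subject_id for s in test_subjects}
    audit = [
        (str(fold_id), name, ids, test_ids)
        for name, ids in (pipe.fitted_subject_ids() if hasattr(pipe, "fitted_subject_ids") else {}).items()
    ]
    # any fitted statistic must only have touched training subjects
    for _, name, ids, _ in audit:
        if not ids <= train_ids:
            raise RuntimeError(f"leakage: {name} touched non-training subjects in fold {fold_id}")
    return fold, audit


def stratified_kfold(subjects, pipeline_factory, k: int = 5, seed: int = 0) -> CVResult:
    """Label-stratified k-fold CV with full per-fold refitting."""
    y = np.array([1 if s.label == "ASD" else 0 for s in subjects])
    minority = min(np.sum(y == 0), np.sum(y == 1))
    if k > len(subjects):
        raise ValueError(f"k={k} exceeds the cohort size {len(subjects)}")
    if k > minority:
        raise ValueError(f"k={k} exceeds the minority class size {minority}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds, audits = [], []
    for fid, (tr, te) in enumerate(skf.split(np.zeros(len(subjects)), y)):
        fold, audit = _run_fold(
            pipeline_factory,
            [subjects[i] for i in tr],
            [subjects[i] for i in te],
            f"fold_{fid}",
        )
        folds.append(fold)
        audits.extend(audit)
    return CVResult(
        scheme="kfold", folds=folds, mean_metrics=_mean_metrics(folds), leakage_audit=audits
    )


def leave_one_site_out(subjects, pipeline_factory) -> CVResult:
    """One fold per site; train on all other sites.

    Sites lacking one of the two classes are skipped with a warning
    (their recall would be undefined).  The mean row is the unweighted
    average over sites.
    """
    sites = sorted({s.site_id for s in subjects})
    if len(sites) < 2:
        raise ValueError("leave-one-site-out needs at least 2 sites")
    folds, audits = [], []
    for site in sites:
        test = [s for s in subjects if s.site_id == site]
        train = [s for s in subjects if s.site_id != site]
        labels = {s.label for s in test}
        if labels < {"ASD", "control"}:
            logger.warning("site %s lacks one class; skipped", site)
            continue
        fold, audit = _run_fold(pipeline_factory, train, test, site)
        folds.append(fold)
        audits.extend(audit)
    if not folds:
        raise ValueError("no site has both classes; cannot evaluate")
    return CVResult(
        scheme="leave_one_site_out",
        folds=folds,
        mean_metrics=_mean_metrics(folds),
        leakage_audit=audits,
    )
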