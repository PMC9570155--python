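"""Evaluation harness: confusion-matrix metrics, ROC/PR, CV, stability.

Eight metrics are reported per evaluation: sensitivity (SE), specificity
(SPC), accuracy (ACC), F1, positive and negative predictive value (PPV,
NPV), the Matthews correlation coefficient (MCC), and the area under the
ROC curve (AUC).  The formulas are the standard ones:

    SE  = TP/(TP+FN)        SPC = TN/(TN+FP)
    ACC = (TP+TN)/n         F1  = 2TP/(2TP+FP+FN)
    PPV = TP/(TP+FP)        NPV = TN/(TN+FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))

A metric whose denominator is zero is reported as ``None`` (undefined),
never silently 0, so small-fold edge cases stay visible.  AUC uses the
trapezoidal/midrank convention, equal to the probability that a random
positive outscores a random negative with ties counted half.

Beyond single evaluations the module provides stratified k-fold
cross-validation of the stacked model (both fold-averaged and pooled
metrics, since the two conventions differ) and a repeated-resampling
stability experiment: draw a balanced subsample, cross-validate, repeat,
and summarise the accuracy spread plus block-of-5 means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from . import model as model_mod
from .errors import ValidationError
from .features import FeatureTable

METRIC_NAMES = ("se", "spc", "acc", "f1", "ppv", "npv", "mcc", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


@dataclass
class MetricsReport:
    """Confusion counts, the eight metrics, and ROC/PR curve points."""

    counts: ConfusionCounts
    se: float | None
    spc: float | None
    acc: float | None
    f1: float | None
    ppv: float | None
    npv: float | None
    mcc: float | None
    auc: float | None
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    pr_points: list[tuple[float, float]] = field(default_factory=list)

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def metrics_from_counts(counts: ConfusionCounts) -> dict[str, float | None]:
    """The seven threshold metrics from a confusion matrix (no AUC)."""
    tp, fn, tn, fp = counts.tp, counts.fn, counts.tn, counts.fp
    mcc_den = np.sqrt(
        float(tp + fn) * float(tp + fp) * float(tn + fp) * float(tn + fn)
    )
    return {
        "se": _ratio(tp, tp + fn),
        "spc": _ratio(tn, tn + fp),
        "acc": _ratio(tp + tn, counts.total),
        "f1": _ratio(2 * tp, 2 * tp + fp + fn),
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
        "mcc": None if mcc_den == 0 else (tp * tn - fp * fn) / mcc_den,
    }


def compute_metrics(
    truth: Sequence[int],
    probs: Sequence[float],
    threshold: float = 0.5,
    curves: bool = True,
) -> MetricsReport:
    """Full eight-metric report at a probability threshold.

    ``truth`` holds 0/1 labels with 1 = ncRNA (positive); ``probs`` the
    predicted positive-class probability.  Classification: positive iff
    prob >= threshold.
    """
    y = np.asarray(truth, dtype=int)
    p = np.asarray(probs, dtype=np.float64)
    if len(y) != len(p):
        raise ValidationError(f"{len(y)} labels but {len(p)} probabilities")
    if len(y) and not set(np.unique(y)) <= {0, 1}:
        raise ValidationError("truth labels must be 0/1")
    pred = (p >= threshold).astype(int)
    counts = ConfusionCounts(
        tp=int(((pred == 1) & (y == 1)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
    )
    m = metrics_from_counts(counts)
    both_classes = len(np.unique(y)) == 2
    auc = float(roc_auc_score(y, p)) if both_classes else None
    roc_points: list[tuple[float, float]] = []
    pr_points: list[tuple[float, float]] = []
    if curves and both_classes:
        fpr, tpr, _ = roc_curve(y, p)
        roc_points = list(zip(fpr.tolist(), tpr.tolist()))
        prec, rec, _ = precision_recall_curve(y, p)
        pr_points = list(zip(rec.tolist(), prec.tolist()))
    return MetricsReport(counts=counts, auc=auc, roc_points=roc_points,
                         pr_points=pr_points, **m)


@dataclass
class CrossValReport:
    """Per-fold reports plus fold-averaged and pooled summaries.

    ``mean``/``sd`` average each metric over the folds where it is defined;
    ``pooled`` recomputes the metrics once from all out-of-fold predictions
    concatenated (the two conventions can differ slightly and reports carry
    both).
    """

    fold_reports: list[MetricsReport]
    pooled: MetricsReport
    mean: dict[str, float | None]
    sd: dict[str, float | None]


def _aggregate(fold_reports: list[MetricsReport]) -> tuple[dict, dict]:
    mean: dict[str, float | None] = {}
    sd: dict[str, float | None] = {}
    for name in METRIC_NAMES:
        vals = [getattr(r, name) for r in fold_reports]
        defined = [v for v in vals if v is not None]
        if defined:
            mean[name] = float(np.mean(defined))
            sd[name] = float(np.std(defined, ddof=1)) if len(defined) > 1 else 0.0
        else:
            mean[name] = None
            sd[name] = None
    return mean, sd


def cross_validate(
    table: FeatureTable,
    subset: Sequence[str],
    folds: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> CrossValReport:
    """Stratified k-fold CV of the stacked model on a feature subset.

    A fresh model bundle is trained per fold; every row is predicted
    exactly once, by the fold that held it out.
    """
    y = table.require_labels().to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("cross-validation requires both classes")
    if counts.min() < folds:
        raise ValidationError(
            f"{folds}-fold CV needs at least {folds} rows per class"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    idx = np.arange(len(y))
    fold_reports: list[MetricsReport] = []
    oof_probs = np.zeros(len(y))
    for tr, te in skf.split(idx, y):
        sub_train = FeatureTable(
            data=table.data.iloc[tr], labels=table.require_labels().iloc[tr]
        )
        bundle = model_mod.train(sub_train, subset, folds=folds, seed=seed)
        sub_test = FeatureTable(data=table.data.iloc[te])
        probs, _ = model_mod.predict(bundle, sub_test)
        oof_probs[te] = probs
        fold_reports.append(
            compute_metrics(y[te], probs, threshold=threshold, curves=False)
        )
    pooled = compute_metrics(y, oof_probs, threshold=threshold)
    mean, sd = _aggregate(fold_reports)
    return CrossValReport(fold_reports=fold_reports, pooled=pooled, mean=mean, sd=sd)


@dataclass
class RepeatResult:
    """Accuracies of repeated balanced-resample CV runs + block means."""

    accuracies: list[float]
    block_means: list[float]  # mean of each complete block of 5 repetitions

    @property
    def spread(self) -> float:
        return max(self.accuracies) - min(self.accuracies)


def repeat_experiment(
    pool: FeatureTable,
    per_class: int = 4000,
    reps: int = 100,
    folds: int = 5,
    seed: int = 0,
    subset: Sequence[str] | None = None,
) -> RepeatResult:
    """Stability experiment: repeated balanced subsampling + CV.

    Each repetition draws ``per_class`` rows per class without replacement
    (fresh sub-seed per repetition), cross-validates the stacked model and
    records the fold-mean accuracy.  ``block_means`` averages consecutive
    blocks of 5 repetitions (incomplete trailing blocks are dropped).
    """
    from .features import FEATURE_NAMES

    y = pool.require_labels()
    if subset is None:
        subset = list(FEATURE_NAMES)
    counts = y.value_counts()
    if len(counts) < 2 or counts.min() < per_class:
        raise ValidationError(
            f"pool needs >= {per_class} rows per class "
            f"(have {counts.to_dict()})"
        )
    rng = np.random.default_rng(seed)
    accs: list[float] = []
    for _ in range(reps):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        rep_rng = np.random.default_rng(sub_seed)
        chosen_idx = []
        for cls in sorted(counts.index):
            members = np.flatnonzero(y.to_numpy() == cls)
            chosen_idx.append(
                rep_rng.choice(members, size=per_class, replace=False)
            )
        rows = np.sort(np.concatenate(chosen_idx))
        sample = FeatureTable(data=pool.data.iloc[rows], labels=y.iloc[rows])
        report = cross_validate(sample, subset, folds=folds, seed=sub_seed)
        accs.append(float(report.mean["acc"]))
    n_blocks = len(accs) // 5
    block_means = [float(np.mean(accs[5 * b : 5 * b + 5])) for b in range(n_blocks)]
    return RepeatResult(accuracies=accs, block_means=block_means)
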