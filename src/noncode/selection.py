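"""Feature-selection strategies.

Four rankers over the 91-feature table, mirroring the study design this
package reproduces:

* ``f_test``        — one-way ANOVA F statistic of each feature against the
                      binary class label, descending;
* ``variance``      — unsupervised: per-feature min-max scaling to [0, 1]
                      followed by ranking on the sample variance of the
                      scaled values (scaling first, because raw features
                      span incomparable scales: length ~1e3 vs frequencies
                      ~1e-2);
* ``vtf``           — the cascade: keep features whose scaled variance is at
                      least the mean scaled variance, then rank the
                      survivors by F and take the top k (default 10);
* ``rf_importance`` — mean impurity-decrease importance from a seeded
                      random forest.

:func:`learning_curve` evaluates ranking prefixes by stratified k-fold CV
accuracy of the default stacked classifier and picks the best prefix
(ties to the smaller prefix).  All rankings break ties by canonical
feature order, so results are platform-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .errors import ValidationError
from .features import FEATURE_NAMES, FeatureTable

logger = logging.getLogger(__name__)

#: Default ten-feature subset for predict-only workflows where no training
#: data is available for re-selection: GC content, the ORF score and
#: coordinates/size, and the T, C, GT, GC, ACG, TAT frequencies — the
#: features the VT-F cascade selects on curated plant transcript benchmarks.
DEFAULT_FEATURE_SUBSET: tuple[str, ...] = (
    "gc_content",
    "score",
    "cds_stop",
    "cds_size",
    "T",
    "C",
    "GT",
    "GC",
    "ACG",
    "TAT",
)

_CANONICAL_INDEX = {name: i for i, name in enumerate(FEATURE_NAMES)}


@dataclass
class SelectionResult:
    """Ranking + chosen prefix for one selection strategy.

    ``ranking`` is best-first; ``scores`` maps feature name to the ranking
    statistic (F value, scaled variance, or importance); ``chosen`` is
    always a prefix of ``ranking``; ``learning_curve`` holds
    (prefix_size, mean CV accuracy) pairs when a curve was run.
    """

    strategy: str
    ranking: list[str]
    scores: dict[str, float]
    chosen: list[str]
    learning_curve: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.ranking)) != len(self.ranking):
            raise ValidationError("ranking contains duplicate feature names")
        unknown = [f for f in self.ranking if f not in _CANONICAL_INDEX]
        if unknown:
            raise ValidationError(f"non-canonical feature name(s): {unknown[:5]}")
        if self.chosen != self.ranking[: len(self.chosen)]:
            raise ValidationError("chosen subset is not a prefix of the ranking")

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "feature": name,
                "statistic": self.scores.get(name, float("nan")),
                "rank": i + 1,
                "kept": int(name in self.chosen),
            }
            for i, name in enumerate(self.ranking)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _rank_by(scores: pd.Series) -> list[str]:
    """Descending by score, ties (and NaN, placed last) by canonical order."""
    def key(name: str) -> tuple[float, int]:
        v = scores[name]
        primary = -v if np.isfinite(v) else (np.inf if np.isnan(v) else -v)
        return (primary, _CANONICAL_INDEX[name])

    return sorted(scores.index, key=key)


def f_statistics(table: FeatureTable) -> pd.Series:
    """Per-feature one-way ANOVA F statistic between the two classes.

    F = (between-group SS / (g-1)) / (within-group SS / (n-g)) with g = 2.
    A feature constant within both classes but different between them has
    infinite F; a feature constant overall has F = 0.
    """
    y = table.require_labels().to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValidationError("F-test requires both classes in the table")
    X = table.matrix()
    n = X.shape[0]
    grand = X.mean(axis=0)
    ss_between = np.zeros(X.shape[1])
    ss_within = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[y == c]
        mc = Xc.mean(axis=0)
        ss_between += len(Xc) * (mc - grand) ** 2
        ss_within += ((Xc - mc) ** 2).sum(axis=0)
    df1 = len(classes) - 1
    df2 = n - len(classes)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df1) / (ss_within / df2)
    f = np.where(ss_between == 0, 0.0, f)  # constant features: F = 0, not NaN
    return pd.Series(f, index=table.data.columns)


def f_test_rank(table: FeatureTable) -> SelectionResult:
    """Rank all features by descending ANOVA F against the labels."""
    f = f_statistics(table)
    ranking = _rank_by(f)
    return SelectionResult(
        strategy="f_test",
        ranking=ranking,
        scores=f.to_dict(),
        chosen=list(ranking),
    )


def scaled_variances(table: FeatureTable) -> pd.Series:
    """Sample variance (ddof=1) of each feature after min-max scaling."""
    if len(table) < 2:
        raise ValidationError("variance ranking requires at least 2 rows")
    X = table.matrix()
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    scaled = np.where(span > 0, (X - lo) / np.where(span > 0, span, 1.0), 0.0)
    return pd.Series(scaled.var(axis=0, ddof=1), index=table.data.columns)


def variance_rank(table: FeatureTable) -> SelectionResult:
    """Rank all features by descending min-max-scaled variance."""
    v = scaled_variances(table)
    ranking = _rank_by(v)
    return SelectionResult(
        strategy="variance_threshold",
        ranking=ranking,
        scores=v.to_dict(),
        chosen=list(ranking),
    )


def vtf_select(table: FeatureTable, k: int = 10) -> SelectionResult:
    """Variance-threshold + F-test cascade; chosen = top-k survivors.

    Stage 1 keeps features whose scaled variance is >= the mean scaled
    variance over all features (inclusive boundary, so the degenerate
    all-equal-variance table keeps everything).  Stage 2 ranks the
    survivors by ANOVA F.  If fewer than k features survive, all survivors
    are chosen and a notice is logged.
    """
    v = scaled_variances(table)
    threshold = v.mean()
    survivors = [name for name in table.data.columns if v[name] >= threshold]
    f = f_statistics(table)
    ranking = _rank_by(f[survivors])
    if len(ranking) < k:
        logger.info(
            "VT-F: only %d features survive the variance threshold (< k=%d); "
            "choosing all survivors",
            len(ranking),
            k,
        )
    chosen = ranking[: min(k, len(ranking))]
    return SelectionResult(
        strategy="vtf",
        ranking=ranking,
        scores=f[survivors].to_dict(),
        chosen=chosen,
    )


def rf_importance_rank(table: FeatureTable, seed: int) -> SelectionResult:
    """Rank features by random-forest mean impurity decrease at a seed."""
    y = table.require_labels().to_numpy()
    if len(np.unique(y)) < 2:
        raise ValidationError("RF importance requires both classes in the table")
    rf = RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
    rf.fit(table.matrix(), y)
    imp = pd.Series(rf.feature_importances_, index=table.data.columns)
    ranking = _rank_by(imp)
    return SelectionResult(
        strategy="rf_importance",
        ranking=ranking,
        scores=imp.to_dict(),
        chosen=list(ranking),
    )


def learning_curve(
    table: FeatureTable,
    result: SelectionResult,
    prefix_sizes: list[int],
    cv_folds: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Pick the best ranking prefix by stratified CV accuracy.

    Runs the default stacked classifier (the package's model module) on
    each prefix and records mean CV accuracy; ``chosen`` becomes the
    highest-accuracy prefix, ties resolved toward fewer features.
    """
    from .model import StackedTranscriptClassifier  # deferred: avoids cycle

    y = table.require_labels().to_numpy()
    _, class_counts = np.unique(y, return_counts=True)
    if cv_folds > class_counts.min():
        raise ValidationError(
            f"cv_folds={cv_folds} exceeds the smallest class count "
            f"({class_counts.min()})"
        )
    curve: list[tuple[int, float]] = []
    for size in prefix_sizes:
        if size > len(result.ranking):
            raise ValidationError(
                f"prefix size {size} exceeds ranking length {len(result.ranking)}"
            )
        subset = result.ranking[:size]
        X = table.matrix(subset)
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        accs = []
        for train_idx, test_idx in skf.split(X, y):
            clf = StackedTranscriptClassifier(seed=seed, folds=cv_folds)
            clf.fit(X[train_idx], y[train_idx])
            pred = (clf.predict_proba(X[test_idx])[:, 1] >= 0.5).astype(int)
            accs.append(float((pred == y[test_idx]).mean()))
        curve.append((size, float(np.mean(accs))))
    best_size = max(curve, key=lambda t: (t[1], -t[0]))[0]
    return SelectionResult(
        strategy=result.strategy,
        ranking=result.ranking,
        scores=result.scores,
        chosen=result.ranking[:best_size],
        learning_curve=curve,
    )
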