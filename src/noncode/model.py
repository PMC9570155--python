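"""Stacked ensemble classifier and model-bundle persistence.

The classifier follows the classic stacking recipe: a fixed menu of base
learners (random forest, extra trees, gradient-boosted trees, logistic
regression, k-nearest neighbours, Gaussian naive Bayes) is trained with
stratified k-fold splitting; each base learner's out-of-fold (OOF) class
probabilities become the training features of a logistic-regression
combiner.  For serving, every base learner is refit on the full training
set.  The OOF construction guarantees the combiner never sees a base
prediction produced by a model that trained on that same row — the fold
bookkeeping needed to verify this is kept on the fitted object.

Features are min-max scaled with the training extremes before any learner
sees them (the scale-sensitive learners need it; trees are unaffected).
A single seed drives fold assignment and every stochastic learner, so
training is exactly repeatable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier

from .errors import BundleError, ValidationError
from .features import FeatureTable

#: Bundle-format version; the major component must match on load.
BUNDLE_FORMAT_VERSION = "1.0"

BASE_LEARNER_NAMES = (
    "random_forest",
    "extra_trees",
    "gradient_boosting",
    "logistic_regression",
    "knn",
    "gaussian_nb",
)


def _base_learners(seed: int) -> dict[str, object]:
    return {
        "random_forest": RandomForestClassifier(
            n_estimators=100, random_state=seed, n_jobs=1
        ),
        "extra_trees": ExtraTreesClassifier(
            n_estimators=100, random_state=seed, n_jobs=1
        ),
        "gradient_boosting": GradientBoostingClassifier(
            n_estimators=100, random_state=seed
        ),
        "logistic_regression": LogisticRegression(max_iter=1000, random_state=seed),
        "knn": KNeighborsClassifier(n_neighbors=5),
        "gaussian_nb": GaussianNB(),
    }


class StackedTranscriptClassifier:
    """One-layer stacking over the fixed base-learner menu.

    sklearn-style: ``fit(X, y)`` then ``predict_proba(X)``.  After fitting,
    the fold bookkeeping is available as ``fold_of_row_`` (which fold held
    out each training row) and ``fold_train_indices_`` (the row indices
    each per-fold model trained on), and the OOF probability matrix as
    ``oof_matrix_`` (one column per base learner, positive class).
    """

    def __init__(self, seed: int = 0, folds: int = 5):
        self.seed = seed
        self.folds = folds

    def fit(self, X: np.ndarray, y: np.ndarray) -> "StackedTranscriptClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=int)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValidationError("training data contains a single class")
        if counts.min() < self.folds:
            raise ValidationError(
                f"need at least {self.folds} members per class for "
                f"{self.folds}-fold stacking; smallest class has {counts.min()}"
            )
        n = len(y)
        skf = StratifiedKFold(n_splits=self.folds, shuffle=True, random_state=self.seed)
        menu = _base_learners(self.seed)
        self.oof_matrix_ = np.zeros((n, len(menu)), dtype=np.float64)
        self.fold_of_row_ = np.full(n, -1, dtype=int)
        self.fold_train_indices_: dict[int, np.ndarray] = {}
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            self.fold_train_indices_[fold] = tr
            self.fold_of_row_[te] = fold
            for j, (name, proto) in enumerate(menu.items()):
                m = clone(proto)
                m.fit(X[tr], y[tr])
                self.oof_matrix_[te, j] = m.predict_proba(X[te])[:, 1]
        self.stacker_ = LogisticRegression(max_iter=1000, random_state=self.seed)
        self.stacker_.fit(self.oof_matrix_, y)
        # refit each base learner on the full training set for serving
        self.base_models_ = {}
        for name, proto in menu.items():
            m = clone(proto)
            m.fit(X, y)
            self.base_models_[name] = m
        return self

    def base_probabilities(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        cols = [
            self.base_models_[name].predict_proba(X)[:, 1]
            for name in BASE_LEARNER_NAMES
        ]
        return np.column_stack(cols) if len(X) else np.zeros((0, len(cols)))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if len(X) == 0:
            return np.zeros((0, 2))
        return self.stacker_.predict_proba(self.base_probabilities(X))


@dataclass
class ModelBundle:
    """Everything needed to reproduce predictions: subset, scaler, stack."""

    feature_subset: tuple[str, ...]
    scaler_min: np.ndarray
    scaler_span: np.ndarray
    classifier: StackedTranscriptClassifier
    seed: int
    version: str = BUNDLE_FORMAT_VERSION

    def transform(self, table: FeatureTable) -> np.ndarray:
        X = table.matrix(self.feature_subset)
        span = np.where(self.scaler_span > 0, self.scaler_span, 1.0)
        return (X - self.scaler_min) / span


def train(
    table: FeatureTable,
    subset: Sequence[str],
    folds: int = 5,
    seed: int = 0,
) -> ModelBundle:
    """Fit the stacked ensemble on a labeled table restricted to ``subset``."""
    y = table.require_labels().to_numpy()
    X = table.matrix(subset)
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    Xs = (X - lo) / np.where(span > 0, span, 1.0)
    clf = StackedTranscriptClassifier(seed=seed, folds=folds)
    clf.fit(Xs, y)
    return ModelBundle(
        feature_subset=tuple(subset),
        scaler_min=lo,
        scaler_span=span,
        classifier=clf,
        seed=seed,
    )


def predict(bundle: ModelBundle, table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-row (prob_ncRNA, predicted class); ncRNA (1) iff prob >= 0.5."""
    Xs = bundle.transform(table)
    if len(Xs) == 0:
        return np.zeros(0), np.zeros(0, dtype=int)
    probs = bundle.classifier.predict_proba(Xs)[:, 1]
    return probs, (probs >= 0.5).astype(int)


def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    """Persist a bundle as a directory: JSON manifest + joblib learners."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": bundle.version,
        "seed": bundle.seed,
        "feature_subset": list(bundle.feature_subset),
        "scaler_min": bundle.scaler_min.tolist(),
        "scaler_span": bundle.scaler_span.tolist(),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    joblib.dump(bundle.classifier, path / "classifier.joblib")


def load_bundle(path: str | Path) -> ModelBundle:
    """Load a bundle directory; refuses on major-version mismatch."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise BundleError(f"not a model bundle (no manifest.json): {path}")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise BundleError(f"corrupted bundle manifest: {exc}") from exc
    version = manifest.get("format_version", "?")
    major = str(version).split(".", 1)[0]
    if major != BUNDLE_FORMAT_VERSION.split(".", 1)[0]:
        raise BundleError(
            f"bundle format version {version} is incompatible with "
            f"{BUNDLE_FORMAT_VERSION}"
        )
    try:
        classifier = joblib.load(path / "classifier.joblib")
    except Exception as exc:  # corrupted pickle -> clean error
        raise BundleError(f"corrupted bundle classifier: {exc}") from exc
    return ModelBundle(
        feature_subset=tuple(manifest["feature_subset"]),
        scaler_min=np.asarray(manifest["scaler_min"], dtype=np.float64),
        scaler_span=np.asarray(manifest["scaler_span"], dtype=np.float64),
        classifier=classifier,
        seed=int(manifest["seed"]),
        version=str(version),
    )
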