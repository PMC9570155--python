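"""Feature-ranking strategies and the learning-curve prefix choice."""

import logging

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from noncode import (
    FEATURE_NAMES,
    ValidationError,
    f_test_rank,
    learning_curve,
    planted_feature_table,
    rf_importance_rank,
    variance_rank,
    vtf_select,
)
from noncode.features import FeatureTable
from noncode.selection import (
    DEFAULT_FEATURE_SUBSET,
    f_statistics,
    scaled_variances,
)

PLANTED = ("gc_content", "score", "cds_size")


def brute_force_f(values: np.ndarray, y: np.ndarray) -> float:
    """Independent one-way ANOVA oracle: explicit SS decomposition."""
    groups = [values[y == c] for c in np.unique(y)]
    n = len(values)
    g = len(groups)
    grand = values.mean()
    ss_between = sum(len(gr) * (gr.mean() - grand) ** 2 for gr in groups)
    ss_within = sum(((gr - gr.mean()) ** 2).sum() for gr in groups)
    if ss_between == 0:
        return 0.0
    if ss_within == 0:
        return float("inf")
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def _table_from_matrix(X, y):
    ids = pd.Index([f"r{i}" for i in range(len(X))], name="id")
    data = pd.DataFrame(X, index=ids, columns=list(FEATURE_NAMES))
    return FeatureTable(data=data, labels=pd.Series(y, index=ids))


class TestFTest:
    def test_matches_brute_force_oracle(self):
        """F values agree with the explicit SS-decomposition oracle, 1e-10."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 91))
        y = np.array([0] * 20 + [1] * 20)
        table = _table_from_matrix(X, y)
        f = f_statistics(table)
        for j, name in enumerate(FEATURE_NAMES):
            assert f[name] == pytest.approx(brute_force_f(X[:, j], y), abs=1e-10)

    def test_identical_feature_has_zero_f(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 91))
        X[:, 0] = 3.14  # constant in both classes
        y = np.array([0] * 10 + [1] * 10)
        f = f_statistics(_table_from_matrix(X, y))
        assert f[FEATURE_NAMES[0]] == 0.0

    def test_perfectly_separated_feature_ranks_first(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 91))
        y = np.array([0] * 4 + [1] * 4)
        X[:, 5] = y  # zero within-class variance, classes apart
        result = f_test_rank(_table_from_matrix(X, y))
        assert result.ranking[0] == FEATURE_NAMES[5]

    def test_f_equals_t_squared_on_two_classes(self):
        """One-way ANOVA F is the square of the pooled two-sample t."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 91))
        y = np.array([0] * 15 + [1] * 15)
        f = f_statistics(_table_from_matrix(X, y))
        for j in (0, 10, 50, 90):
            t, _ = stats.ttest_ind(X[y == 0, j], X[y == 1, j], equal_var=True)
            assert f[FEATURE_NAMES[j]] == pytest.approx(t**2, abs=1e-8)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(5)
        table = _table_from_matrix(rng.normal(size=(10, 91)), np.zeros(10, dtype=int))
        with pytest.raises(ValidationError):
            f_test_rank(table)


class TestVarianceRank:
    def test_constant_feature_ranked_last(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 91))
        X[:, 30] = 7.0
        result = variance_rank(_table_from_matrix(X, np.zeros(20, dtype=int)))
        assert result.ranking[-1] == FEATURE_NAMES[30]
        assert result.scores[FEATURE_NAMES[30]] == 0.0

    def test_alternating_binary_feature_has_maximal_scaled_variance(self):
        n = 20
        rng = np.random.default_rng(7)
        X = rng.uniform(size=(n, 91))
        X[:, 0] = np.tile([0.0, 1.0], n // 2)
        v = scaled_variances(_table_from_matrix(X, np.zeros(n, dtype=int)))
        assert v[FEATURE_NAMES[0]] == pytest.approx(0.25 * n / (n - 1))
        assert v[FEATURE_NAMES[0]] == v.max()

    def test_matches_brute_force_variance(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(25, 91))
        table = _table_from_matrix(X, np.zeros(25, dtype=int))
        v = scaled_variances(table)
        for j in range(10):
            col = X[:, j]
            scaled = (col - col.min()) / (col.max() - col.min())
            assert v[FEATURE_NAMES[j]] == pytest.approx(scaled.var(ddof=1), abs=1e-12)

    def test_fewer_than_two_rows_rejected(self):
        rng = np.random.default_rng(9)
        table = _table_from_matrix(rng.normal(size=(1, 91)), np.zeros(1, dtype=int))
        with pytest.raises(ValidationError):
            variance_rank(table)


class TestVtfSelect:
    def test_equal_variance_keeps_all(self):
        """The variance boundary is inclusive: all-equal variances survive."""
        n = 20
        rng = np.random.default_rng(10)
        base = rng.uniform(size=n)
        X = np.tile(base[:, None], (1, 91))  # identical columns -> equal variance
        y = np.array([0, 1] * (n // 2))
        result = vtf_select(_table_from_matrix(X, y), k=10)
        assert len(result.ranking) == 91

    def test_planted_features_recovered_in_top_ten(self, planted_table):
        result = vtf_select(planted_table, k=10)
        assert set(PLANTED) <= set(result.chosen)
        assert len(result.chosen) == 10

    def test_chosen_subset_of_variance_survivors(self, planted_table):
        v = scaled_variances(planted_table)
        survivors = {n for n in v.index if v[n] >= v.mean()}
        result = vtf_select(planted_table, k=10)
        assert set(result.chosen) <= survivors

    def test_k_larger_than_survivors_logs_notice(self, planted_table, caplog):
        with caplog.at_level(logging.INFO, logger="noncode.selection"):
            result = vtf_select(planted_table, k=1000)
        assert result.chosen == result.ranking
        assert any("survive" in r.message for r in caplog.records)


class TestRfImportance:
    def test_planted_features_in_top_ten(self, planted_table):
        result = rf_importance_rank(planted_table, seed=0)
        assert set(PLANTED) <= set(result.ranking[:10])

    def test_noise_importances_stay_flat(self, noise_table):
        result = rf_importance_rank(noise_table, seed=0)
        imps = np.array([result.scores[n] for n in FEATURE_NAMES])
        assert imps.max() <= 3.0 * imps.mean()

    def test_deterministic_given_seed(self, planted_table):
        r1 = rf_importance_rank(planted_table, seed=3)
        r2 = rf_importance_rank(planted_table, seed=3)
        assert r1.ranking == r2.ranking
        assert r1.scores == r2.scores


class TestLearningCurve:
    def test_informative_prefix_beats_noise_prefix(self, planted_table):
        base = f_test_rank(planted_table)
        # informative features rank at the top; a 3-prefix holds them all
        curve = learning_curve(planted_table, base, [3], cv_folds=5, seed=0)
        top3_acc = curve.learning_curve[0][1]
        # rank the same table by *ascending* F: a pure-noise prefix
        noise_ranking = base.ranking[::-1]
        from noncode.selection import SelectionResult

        noise = SelectionResult(
            strategy="f_test",
            ranking=noise_ranking,
            scores=base.scores,
            chosen=noise_ranking,
        )
        noise_curve = learning_curve(planted_table, noise, [3], cv_folds=5, seed=0)
        assert top3_acc > noise_curve.learning_curve[0][1]

    def test_single_prefix_is_chosen(self, planted_table):
        base = f_test_rank(planted_table)
        result = learning_curve(planted_table, base, [5], cv_folds=5, seed=0)
        assert result.chosen == base.ranking[:5]

    def test_chosen_prefix_small_once_planted_included(self, planted_table):
        base = f_test_rank(planted_table)
        result = learning_curve(planted_table, base, [3, 10, 30], cv_folds=5, seed=0)
        assert set(PLANTED) <= set(result.chosen)
        assert len(result.chosen) <= 10

    def test_oversized_prefix_rejected(self, planted_table):
        base = f_test_rank(planted_table)
        with pytest.raises(ValidationError):
            learning_curve(planted_table, base, [92], cv_folds=5, seed=0)


class TestContracts:
    def test_rankings_are_permutations(self, planted_table):
        for result in (
            f_test_rank(planted_table),
            variance_rank(planted_table),
            rf_importance_rank(planted_table, seed=0),
        ):
            assert sorted(result.ranking) == sorted(FEATURE_NAMES)

    def test_default_subset_is_canonical(self):
        assert len(DEFAULT_FEATURE_SUBSET) == 10
        assert set(DEFAULT_FEATURE_SUBSET) <= set(FEATURE_NAMES)
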