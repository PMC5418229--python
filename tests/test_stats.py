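"""Statistical layer: exact Mann-Whitney enumeration, partial-correlation
oracles, Bonferroni thresholds and the cross-validated classifier."""

import numpy as np
import pytest

from repolpop.stats import (bonferroni_threshold, hs_classifier_cv,
                            mann_whitney_u, partial_correlation,
                            partial_correlation_matrix)


class TestMannWhitney:
    def test_exact_enumeration_small_sample(self):
        r = mann_whitney_u([1, 2], [3, 4])
        assert r.method == "exact"
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1.0 / 3.0)

    def test_identical_groups_p_one(self):
        r = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert r.p_value == pytest.approx(1.0)

    def test_strong_separation_tiny_p(self):
        a = np.arange(50) + 1000.0
        b = np.arange(50)
        r = mann_whitney_u(a, b)
        assert r.method == "asymptotic"
        assert r.p_value < 1e-10

    def test_symmetry_in_group_order(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 15)
        assert mann_whitney_u(a, b).p_value == pytest.approx(
            mann_whitney_u(b, a).p_value)
        a2, b2 = rng.normal(0, 1, 5), rng.normal(1, 1, 5)
        assert mann_whitney_u(a2, b2).p_value == pytest.approx(
            mann_whitney_u(b2, a2).p_value)

    def test_ties_handled_in_exact_mode(self):
        r = mann_whitney_u([1, 1, 2], [1, 2, 2])
        assert r.method == "exact"
        assert 0 < r.p_value <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1, 2])


def _residual_regression_pcc(X, i, j):
    """Independent oracle: correlate the residuals of i and j after
    regressing each on all remaining columns."""
    rest = [k for k in range(X.shape[1]) if k not in (i, j)]
    A = np.column_stack([X[:, rest], np.ones(len(X))])
    ri = X[:, i] - A @ np.linalg.lstsq(A, X[:, i], rcond=None)[0]
    rj = X[:, j] - A @ np.linalg.lstsq(A, X[:, j], rcond=None)[0]
    return np.corrcoef(ri, rj)[0, 1]


class TestPartialCorrelation:
    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(1000, 4))
        assert abs(partial_correlation(X, 0, 1)) < 0.1

    def test_three_variable_closed_form(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=2000)
        x = 0.8 * z + 0.6 * rng.normal(size=2000)
        y = -0.5 * z + 0.9 * rng.normal(size=2000)
        X = np.column_stack([x, y, z])
        r = np.corrcoef(X, rowvar=False)
        expected = ((r[0, 1] - r[0, 2] * r[1, 2])
                    / np.sqrt((1 - r[0, 2] ** 2) * (1 - r[1, 2] ** 2)))
        assert partial_correlation(X, 0, 1) == pytest.approx(expected,
                                                             abs=1e-10)

    def test_matches_residual_regression_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 6))
        X[:, 0] += 0.5 * X[:, 3]
        X[:, 1] += -0.7 * X[:, 3] + 0.2 * X[:, 0]
        for i, j in [(0, 1), (2, 4), (1, 3)]:
            assert partial_correlation(X, i, j) == pytest.approx(
                _residual_regression_pcc(X, i, j), abs=1e-10)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(150, 5))
        p = partial_correlation_matrix(X)
        np.testing.assert_allclose(p, p.T, atol=1e-12)
        Y = X.copy()
        Y[:, 2] = 3.7 * Y[:, 2] - 11.0
        assert partial_correlation(Y, 0, 1) == pytest.approx(
            partial_correlation(X, 0, 1), abs=1e-10)

    def test_errors(self):
        with pytest.raises(ValueError):
            partial_correlation(np.ones((10, 3)), 0, 1)  # constant columns
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            partial_correlation(rng.normal(size=(5, 4)), 0, 1)  # too few obs


class TestBonferroni:
    @pytest.mark.parametrize("alpha, m", [(0.05, 36), (0.05, 27), (0.05, 1)])
    def test_threshold(self, alpha, m):
        assert bonferroni_threshold(alpha, m) == alpha / m

    def test_errors(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 3)


def _separable_data(n=120, seed=0):
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 4 == 0           # ~25% positive class
    X = rng.normal(size=(n, 7)) * 0.3
    X[y, 0] += 10.0                     # huge margin on one feature
    return X, y


class TestClassifier:
    def test_separable_classes_high_sensitivity(self):
        X, y = _separable_data()
        ev = hs_classifier_cv(X, y, iterations=5, seed=1)
        assert ev.mean_sensitivity > 0.99

    def test_no_signal_is_near_chance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 7))
        y = np.arange(200) % 2 == 0     # balanced labels independent of X
        ev = hs_classifier_cv(X, y, iterations=5, seed=3)
        assert 0.2 < ev.mean_sensitivity < 0.8

    def test_seed_reproducibility(self):
        X, y = _separable_data(seed=5)
        a = hs_classifier_cv(X, y, iterations=3, seed=7)
        b = hs_classifier_cv(X, y, iterations=3, seed=7)
        assert a.per_iteration == b.per_iteration

    def test_feature_order_and_affine_invariance(self):
        X, y = _separable_data(seed=6)
        base = hs_classifier_cv(X, y, iterations=2, seed=9)
        perm = hs_classifier_cv(X[:, ::-1], y, iterations=2, seed=9)
        assert perm.per_iteration == pytest.approx(base.per_iteration)
        scaled = hs_classifier_cv(X * 13.0 - 5.0, y, iterations=2, seed=9)
        assert scaled.per_iteration == pytest.approx(base.per_iteration)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.raises(ValueError):
            hs_classifier_cv(X, np.ones(20, dtype=bool))
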