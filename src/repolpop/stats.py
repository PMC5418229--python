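"""Statistical layer: group tests, partial correlation, multiplicity control
and the susceptibility classifier.

Group differences in biomarker values use the Mann-Whitney U-test (exact
permutation enumeration for small samples, tie-corrected normal
approximation otherwise).  Dependence between co-varying conductances uses
partial correlation coefficients -- the correlation between two conductances
controlling for all remaining ones -- computed by precision-matrix
normalization, with Bonferroni-corrected significance thresholds.  A
logistic-regression classifier predicts high susceptibility from z-scored
biomarkers under repeated stratified 10-fold cross-validation; its headline
metric is sensitivity (recall of the highly susceptible class).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "TestResult",
    "ClassifierEvaluation",
    "mann_whitney_u",
    "partial_correlation",
    "partial_correlation_matrix",
    "bonferroni_threshold",
    "hs_classifier_cv",
]

#: combined sample size at or below which the exact permutation p is used
EXACT_N_MAX = 12


@dataclass
class TestResult:
    statistic: float       # U of the first sample
    p_value: float         # two-sided
    n_a: int
    n_b: int
    method: str            # "exact" | "asymptotic"
    corrected_alpha: Optional[float] = None


def _exact_mwu_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by enumerating all assignments of the pooled values
    to the two groups (handles ties since it permutes the values
    themselves): p = min(1, 2 * min(P(U <= u), P(U >= u)))."""
    pooled = np.concatenate([a, b])
    na = len(a)
    n_total = len(pooled)
    idx = range(n_total)
    us = []
    for pick in combinations(idx, na):
        mask = np.zeros(n_total, dtype=bool)
        mask[list(pick)] = True
        ga, gb = pooled[mask], pooled[~mask]
        u = sum(np.sum(x > gb) + 0.5 * np.sum(x == gb) for x in ga)
        us.append(u)
    us = np.asarray(us)
    n_perm = comb(n_total, na)
    p_le = np.sum(us <= u_obs + 1e-12) / n_perm
    p_ge = np.sum(us >= u_obs - 1e-12) / n_perm
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def mann_whitney_u(a: Sequence[float], b: Sequence[float],
                   corrected_alpha: Optional[float] = None) -> TestResult:
    """Two-sided Mann-Whitney U-test.

    Exact enumeration of the permutation distribution when the combined
    sample size is at most 12; otherwise the tie-corrected normal
    approximation (with continuity correction).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u_a = float(sum(np.sum(x > b) + 0.5 * np.sum(x == b) for x in a))
    if a.size + b.size <= EXACT_N_MAX:
        p = _exact_mwu_p(a, b, u_a)
        method = "exact"
    else:
        p = float(sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="asymptotic").pvalue)
        method = "asymptotic"
    return TestResult(u_a, p, int(a.size), int(b.size), method,
                      corrected_alpha)


def partial_correlation(data, i: int, j: int) -> float:
    """Partial correlation between columns i and j of an observations x
    variables matrix, controlling for all remaining columns.

    Computed by normalizing the precision matrix:
    pcc(i, j | rest) = -P_ij / sqrt(P_ii * P_jj).
    """
    return float(partial_correlation_matrix(data)[i, j])


def partial_correlation_matrix(data) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    n, m = data.shape
    if n <= m + 2:
        raise ValueError("need more observations than variables + 2")
    sd = data.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant column in data")
    cov = np.cov(data, rowvar=False)
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular covariance matrix") from exc
    d = np.sqrt(np.outer(np.diag(prec), np.diag(prec)))
    pcc = -prec / d
    np.fill_diagonal(pcc, 1.0)
    return pcc


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison significance threshold alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


@dataclass
class ClassifierEvaluation:
    mean_sensitivity: float
    per_iteration: List[float]
    folds: int
    iterations: int
    seed: int


def hs_classifier_cv(features, labels, folds: int = 10, iterations: int = 1,
                     seed: int = 0, threshold: float = 0.5
                     ) -> ClassifierEvaluation:
    """Repeated stratified k-fold evaluation of a logistic-regression
    classifier of the positive (highly susceptible) class.

    Per iteration the folds are reshuffled; features are z-scored using
    training-fold statistics only; an unpenalized logistic regression is fit
    and held-out models are classified at the given probability threshold.
    Sensitivity is the fraction of true positives classified positive, with
    every model tested exactly once per iteration.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(bool)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be 2-D with one row per label")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")

    rng = np.random.default_rng(seed)
    per_iter = []
    for _ in range(iterations):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        tp = fn = 0
        for train, test in skf.split(X, y):
            mu = X[train].mean(axis=0)
            sd = X[train].std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            Xtr = (X[train] - mu) / sd
            Xte = (X[test] - mu) / sd
            # C=inf: plain maximum likelihood, no regularization
            clf = LogisticRegression(C=np.inf, solver="lbfgs",
                                     max_iter=2000)
            clf.fit(Xtr, y[train])
            pos = clf.classes_.tolist().index(True)
            pred = clf.predict_proba(Xte)[:, pos] > threshold
            tp += int(np.sum(pred & y[test]))
            fn += int(np.sum(~pred & y[test]))
        per_iter.append(tp / (tp + fn))
    return ClassifierEvaluation(float(np.mean(per_iter)), per_iter,
                                folds, iterations, seed)
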