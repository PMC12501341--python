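"""Nonparametric AUC estimation and the DeLong covariance of correlated
AUCs via structural components (placement values).

The AUC is the Mann-Whitney probability that a random case outranks a
random control, with midrank handling of ties.  For k prediction scores
evaluated on the same participants, the placement-value decomposition
gives a consistent estimate of the joint covariance of the k AUC
estimates, enabling a global chi-square contrast test and pairwise
z-tests between correlated curves.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm, rankdata


def _placements(cases: np.ndarray, controls: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus per-case (V10) and per-control (V01) placement values."""
    m, n = len(cases), len(controls)
    combined = np.concatenate([cases, controls])
    r_all = rankdata(combined, method="average")
    r_cases = rankdata(cases, method="average")
    r_controls = rankdata(controls, method="average")
    # midrank identity: V10_i = P(X_i > Y) + 0.5 P(X_i = Y)
    v10 = (r_all[:m] - r_cases) / n
    v01 = 1.0 - (r_all[m:] - r_controls) / m
    auc = v10.mean()
    return auc, v10, v01


def auc_mann_whitney(scores, outcome) -> float:
    """Midrank Mann-Whitney AUC of ``scores`` for binary ``outcome``."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both outcome classes must be present")
    auc, _, _ = _placements(scores[y], scores[~y])
    return auc


def delong_covariance(score_matrix, outcome) -> tuple[np.ndarray, np.ndarray]:
    """AUCs and their DeLong covariance for k scores on one sample.

    ``score_matrix`` is (n, k); returns (aucs shape (k,), cov shape (k, k)).
    """
    X = np.atleast_2d(np.asarray(score_matrix, dtype=float))
    if X.ndim != 2:
        raise ValueError("score_matrix must be 2-D")
    y = np.asarray(outcome, dtype=bool)
    if not y.any() or y.all():
        raise ValueError("both outcome classes must be present")
    m, n = int(y.sum()), int((~y).sum())
    k = X.shape[1]
    aucs = np.empty(k)
    V10 = np.empty((m, k))
    V01 = np.empty((n, k))
    for j in range(k):
        aucs[j], V10[:, j], V01[:, j] = _placements(X[y, j], X[~y, j])
    s10 = np.cov(V10, rowvar=False, ddof=1).reshape(k, k) if m > 1 else np.zeros((k, k))
    s01 = np.cov(V01, rowvar=False, ddof=1).reshape(k, k) if n > 1 else np.zeros((k, k))
    cov = s10 / m + s01 / n
    return aucs, cov


def auc_confint(auc: float, var: float, level: float = 0.95) -> tuple[float, float]:
    """Wald interval on the AUC scale, clipped to [0, 1]."""
    zq = norm.ppf(0.5 + level / 2)
    half = zq * np.sqrt(max(var, 0.0))
    return max(0.0, auc - half), min(1.0, auc + half)


def global_auc_test(aucs: np.ndarray, cov: np.ndarray) -> tuple[float, float, int]:
    """Chi-square contrast test that all k AUCs are equal.

    Contrasts each AUC against the first (a common reference); the
    quadratic form uses the pseudo-inverse so exactly-identical curves
    (zero contrast, zero variance) degrade gracefully to p = 1.
    Returns (statistic, p, df).
    """
    k = len(aucs)
    if k < 2:
        raise ValueError("need at least two models")
    L = np.hstack([-np.ones((k - 1, 1)), np.eye(k - 1)])
    d = L @ aucs
    vd = L @ cov @ L.T
    stat = float(d @ np.linalg.pinv(vd, rcond=1e-12) @ d)
    df = k - 1
    return stat, float(chi2_dist.sf(stat, df)), df


def pairwise_z_test(aucs: np.ndarray, cov: np.ndarray, i: int, j: int) -> tuple[float, float]:
    """Two-sided DeLong z-test between curves i and j; identical curves
    (zero difference and zero variance) give p = 1."""
    diff = aucs[i] - aucs[j]
    var = cov[i, i] + cov[j, j] - 2 * cov[i, j]
    if var <= 0:
        return (0.0, 1.0) if abs(diff) < 1e-12 else (np.inf, 0.0)
    z = diff / np.sqrt(var)
    return float(z), float(2 * norm.sf(abs(z)))
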