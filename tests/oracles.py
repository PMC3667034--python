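"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — dense matrices, explicit formulas,
exhaustive enumeration — and shares no code path with the package internals
it checks.
"""

import math

import numpy as np
from scipy.linalg import toeplitz
from scipy.stats import multivariate_normal

_COV = ["age", "season", "dpv"]


def ar_autocovariances(gamma, sigma2, n_lags):
    """Autocovariances of a stationary AR(q) via the Yule-Walker linear system."""
    gamma = np.asarray(gamma, dtype=float)
    q = len(gamma)
    if q == 0:
        g = np.zeros(n_lags + 1)
        g[0] = sigma2
        return g
    # solve for g_0..g_q from the Yule-Walker equations
    A = np.zeros((q + 1, q + 1))
    b = np.zeros(q + 1)
    A[0, 0] = 1.0
    for r in range(1, q + 1):
        A[0, r] -= gamma[r - 1]
    b[0] = sigma2
    for k in range(1, q + 1):
        A[k, k] = 1.0
        for r in range(1, q + 1):
            A[k, abs(k - r)] -= gamma[r - 1]
    g_head = np.linalg.solve(A, b)
    g = np.zeros(max(n_lags + 1, q + 1))
    g[: q + 1] = g_head
    for k in range(q + 1, n_lags + 1):
        g[k] = gamma @ g[k - q : k][::-1]
    return g[: n_lags + 1]


def dense_transition_loglik(params, cohort):
    """Transition-model log-likelihood via explicit multivariate normals."""
    beta = np.asarray(params.beta)
    mu = params.alpha / (1.0 - sum(params.gamma))
    total = 0.0
    for _, g in cohort.groupby_donor():
        T = len(g)
        x = g[_COV].to_numpy(dtype=float)
        z = g["hb"].to_numpy(dtype=float) - x @ beta - mu
        acv = ar_autocovariances(params.gamma, params.sigma2_eps, T - 1)
        total += multivariate_normal.logpdf(z, mean=np.zeros(T), cov=toeplitz(acv))
    return float(total)


def dense_reml(d_diag, sigma2_eps, cohort, structure):
    """REML criterion assembled from the full block-diagonal V."""
    df = cohort.data
    n = len(df)
    X = np.column_stack([np.ones(n), df[_COV].to_numpy(dtype=float)])
    y = df["hb"].to_numpy(dtype=float)
    k = {"RI": 1, "RIRS": 2}[structure]
    V = np.zeros((n, n))
    i0 = 0
    for _, g in cohort.groupby_donor():
        T = len(g)
        Z = X[i0 : i0 + T, :k]
        V[i0 : i0 + T, i0 : i0 + T] = Z @ np.diag(d_diag[:k]) @ Z.T + sigma2_eps * np.eye(T)
        i0 += T
    Vi = np.linalg.inv(V)
    XtVX = X.T @ Vi @ X
    beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
    r = y - X @ beta
    p = X.shape[1]
    return -0.5 * (
        np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtVX)[1]
        + r @ Vi @ r
        + (n - p) * math.log(2 * math.pi)
    )


def pairwise_auc(truth, score):
    """AUC by exhaustive concordant-pair counting (ties count 0.5)."""
    truth = np.asarray(truth, bool)
    score = np.asarray(score, float)
    pos = score[truth]
    neg = score[~truth]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
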