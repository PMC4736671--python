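"""Independent brute-force implementations used as test oracles.

Everything here works directly on dense record-level matrices with plain
numpy inversions and textbook formulas, deliberately sharing no code with
the package's computational paths.
"""

from __future__ import annotations

import numpy as np


def reml_loglik_dense(y, W, G, D, sigma_a2, sigma_d2, sigma_pe2, sigma_e2):
    """Restricted log-likelihood by explicit V construction and inversion."""
    y = np.asarray(y, dtype=float)
    W = np.asarray(W, dtype=float)
    n = y.size
    n_anim = W.shape[1]
    K = sigma_a2 * np.asarray(G) + sigma_pe2 * np.eye(n_anim)
    if D is not None and sigma_d2:
        K = K + sigma_d2 * np.asarray(D)
    V = W @ K @ W.T + sigma_e2 * np.eye(n)
    X = np.ones((n, 1))
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    beta = np.linalg.solve(XVX, X.T @ Vi @ y)
    r = y - X @ beta
    sign, logdet_v = np.linalg.slogdet(V)
    assert sign > 0
    return float(
        -0.5 * ((n - 1) * np.log(2 * np.pi) + logdet_v + np.log(XVX[0, 0]) + r @ Vi @ r)
    )


def blup_dense(y, W, G, D, sigma_a2, sigma_d2, sigma_pe2, sigma_e2):
    """Conditional-expectation (GLS) solutions by dense inversion."""
    y = np.asarray(y, dtype=float)
    W = np.asarray(W, dtype=float)
    n = y.size
    n_anim = W.shape[1]
    G = np.asarray(G)
    K = sigma_a2 * G + sigma_pe2 * np.eye(n_anim)
    if D is not None and sigma_d2:
        K = K + sigma_d2 * np.asarray(D)
    V = W @ K @ W.T + sigma_e2 * np.eye(n)
    X = np.ones((n, 1))
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    Py = Vi @ (y - X @ beta)
    u = sigma_a2 * G @ W.T @ Py
    d = sigma_d2 * np.asarray(D) @ W.T @ Py if D is not None and sigma_d2 else np.zeros(n_anim)
    pe = sigma_pe2 * W.T @ Py
    return u, d, pe


def grm_dense(X, p, kind):
    """Relationship matrix by explicit coding and matrix product."""
    X = np.asarray(X, dtype=float)
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    poly = (p > 0) & (p < 1)
    if kind == "additive":
        C = X - 2.0 * p
        denom = (2 * p * q)[poly].sum()
    else:
        C = np.empty_like(X)
        for j in range(X.shape[1]):
            codes = {0: -2 * p[j] ** 2, 1: 2 * p[j] * q[j], 2: -2 * q[j] ** 2}
            C[:, j] = [codes[int(v)] for v in X[:, j]]
        denom = ((2 * p * q) ** 2)[poly].sum()
    C[:, ~poly] = 0.0
    return C @ C.T / denom


def g_f_dense(X, p):
    """Per-animal inbreeding coefficient by per-SNP summation."""
    X = np.asarray(X, dtype=float)
    p = np.asarray(p, dtype=float)
    out = []
    for row in X:
        terms = []
        for j in range(X.shape[1]):
            pj, xj = p[j], row[j]
            if pj <= 0 or pj >= 1:
                continue
            if pj < 0.5:  # count the most common allele
                pj, xj = 1 - pj, 2 - xj
            terms.append((xj**2 - (1 + 2 * pj) * xj + 2 * pj**2) / (2 * pj * (1 - pj)))
        out.append(np.mean(terms))
    return np.array(out)


def pearson_dense(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    cx, cy = x - x.mean(), y - y.mean()
    denom = np.sqrt((cx @ cx) * (cy @ cy))
    if denom == 0.0:
        return float("nan")
    return float((cx @ cy) / denom)


def spearman_dense(x, y):
    """Rank-then-Pearson with midranks for ties."""

    def midrank(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(v.size, float)
        i = 0
        sv = v[order]
        while i < v.size:
            j = i
            while j + 1 < v.size and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    return pearson_dense(midrank(x), midrank(y))


def slope_dense(y, x):
    """Least-squares slope of y on x with intercept."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.ptp(x) == 0.0:
        return float("nan")
    X = np.column_stack([np.ones_like(x), x])
    coef = np.linalg.solve(X.T @ X, X.T @ y)
    return float(coef[1])


def paired_t_dense(a, b):
    """Classic paired t statistic and two-sided p over k folds."""
    from scipy import stats

    d = np.asarray(a, float) - np.asarray(b, float)
    k = d.size
    t = d.mean() / (d.std(ddof=1) / np.sqrt(k))
    p = 2 * stats.t.sf(abs(t), df=k - 1)
    return float(t), float(p)
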