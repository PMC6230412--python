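"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity by the most transparent route available
(double loops, exhaustive enumeration, explicit refitting), deliberately
avoiding the code paths it is used to check.
"""

import itertools

import numpy as np


def scatter_bruteforce(X, labels):
    """Within/between-class scatter via explicit double loops."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    K = X.shape[0]
    m = X.mean(axis=1)
    S_W = np.zeros((K, K))
    S_B = np.zeros((K, K))
    for cls in np.unique(labels):
        cols = np.flatnonzero(labels == cls)
        m_i = X[:, cols].mean(axis=1)
        for k in cols:
            d = X[:, k] - m_i
            S_W += np.outer(d, d)
        d = m_i - m
        S_B += cols.size * np.outer(d, d)
    return S_W, S_B


def fidelity_bruteforce(dataset, D, X):
    """Term-by-term discriminative fidelity, one Frobenius norm at a time."""
    total = 0.0
    for i in range(1, dataset.c + 1):
        Ai = dataset.class_samples(i)
        Xi = X[:, dataset.class_slices[i - 1]]
        total += np.linalg.norm(Ai - D.D @ Xi, "fro") ** 2
        Di = D.block(i)
        Xii = Xi[D.class_blocks[i - 1], :]
        total += np.linalg.norm(Ai - Di @ Xii, "fro") ** 2
        for j in range(1, dataset.c + 1):
            if j == i:
                continue
            Dj = D.block(j)
            Xij = Xi[D.class_blocks[j - 1], :]
            total += np.linalg.norm(Dj @ Xij, "fro") ** 2
    return total


def lasso_sign_enumeration(D, a, lam):
    """Global minimum of ||a - D x||^2 + lam ||x||_1 by enumerating all
    3^K support/sign patterns and solving each restricted stationarity
    system.  Every candidate is feasible, and the optimum's own pattern is
    among them, so the minimum over candidates is exact."""
    K = D.shape[1]
    best = np.inf
    for signs in itertools.product((-1.0, 0.0, 1.0), repeat=K):
        s = np.array(signs)
        support = s != 0
        x = np.zeros(K)
        if support.any():
            Ds = D[:, support]
            rhs = Ds.T @ a - lam * s[support] / 2.0
            try:
                x[support] = np.linalg.solve(Ds.T @ Ds, rhs)
            except np.linalg.LinAlgError:
                x[support] = np.linalg.lstsq(Ds, a, rcond=None)[0]
        val = np.sum((a - D @ x) ** 2) + lam * np.sum(np.abs(x))
        best = min(best, val)
    return best


def ridge_beta_lstsq(H, Y, C):
    """Minimizer of ||beta||^2 + C ||H beta - Y||^2 via the augmented
    least-squares system [sqrt(C) H; I] beta = [sqrt(C) Y; 0] solved by QR
    (numpy lstsq) — an independent route to the ridge solution."""
    N, m = H.shape
    q = Y.shape[1]
    top = np.sqrt(C) * H
    aug = np.vstack([top, np.eye(m)])
    rhs = np.vstack([np.sqrt(C) * Y, np.zeros((m, q))])
    beta, *_ = np.linalg.lstsq(aug, rhs, rcond=None)
    return beta


def explicit_loo_mse(H, Y, C, solve):
    """Leave-one-out MSE by literally refitting without each sample."""
    N = H.shape[0]
    errs = []
    for j in range(N):
        keep = np.arange(N) != j
        beta = solve(H[keep], Y[keep], C)
        errs.append((Y[j] - H[j] @ beta) ** 2)
    return float(np.mean(errs))
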