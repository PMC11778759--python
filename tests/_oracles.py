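"""Independent reference implementations used only to check the solvers.

These deliberately share no code with the package's iterative solvers:
the elastic-net oracle enumerates KKT sign patterns and solves linear
systems; the CV oracle is a plain fold loop; the graphical-lasso oracle
is an ADMM splitting with exact proximal steps.
"""

from __future__ import annotations

import itertools

import numpy as np


def kkt_elastic_net(X, y, alpha: float, lam: float) -> np.ndarray:
    """Exact elastic-net solution by exhaustive sign-pattern enumeration.

    Solves argmin (1/(2n))||y - b0 - Xb||^2
                 + lam [ (1-alpha)/2 ||b||^2 + alpha ||b||_1 ]
    for small q by trying every sign pattern in {-1, 0, +1}^q, solving
    the smooth stationarity system on the active set and verifying the
    subgradient conditions.  ``X`` here has NO intercept column; the
    returned vector is [b0, b].
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, q = X.shape
    xbar = X.mean(axis=0)
    ybar = y.mean()
    Xc = X - xbar
    yc = y - ybar
    G = Xc.T @ Xc / n
    c = Xc.T @ yc / n
    l1 = lam * alpha
    l2 = lam * (1.0 - alpha)

    if l1 == 0.0:
        b = np.linalg.solve(G + l2 * np.eye(q), c)
        return np.concatenate([[ybar - xbar @ b], b])

    tol = 1e-10
    for signs in itertools.product((-1, 0, 1), repeat=q):
        s = np.array(signs, dtype=float)
        active = s != 0
        b = np.zeros(q)
        if active.any():
            A = G[np.ix_(active, active)] + l2 * np.eye(int(active.sum()))
            rhs = c[active] - l1 * s[active]
            b[active] = np.linalg.solve(A, rhs)
            if np.any(b[active] * s[active] < -tol):
                continue
        grad_inactive = c[~active] - G[~active][:, active] @ b[active] \
            if active.any() else c[~active]
        if np.any(np.abs(grad_inactive) > l1 + 1e-9):
            continue
        return np.concatenate([[ybar - xbar @ b], b])
    raise AssertionError("no KKT-consistent sign pattern found")


def naive_cv_curve(X, y, alpha, Q, grid, seed, solver, fold_fn):
    """Plain fold-loop CV: returns (mse, se) arrays over the grid.

    ``solver(X, y, alpha, lam)`` fits one response; ``fold_fn(n, Q, seed)``
    supplies the same partition the production code uses (the partition
    itself is a shared, deterministic helper).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    folds = fold_fn(n, Q, seed)
    fold_mse = np.empty((Q, len(grid)))
    for qi, test_idx in enumerate(folds):
        train = np.setdiff1d(np.arange(n), test_idx)
        for s, lam in enumerate(grid):
            b = solver(X[train], y[train], alpha, lam)
            resid = y[test_idx] - X[test_idx] @ b
            fold_mse[qi, s] = resid @ resid / len(test_idx)
    return fold_mse.mean(axis=0), fold_mse.std(axis=0, ddof=1) / np.sqrt(Q)


def admm_glasso(S, rho, t=1.0, max_iter=20000, tol=1e-11):
    """Graphical lasso by ADMM with exact proximal steps.

    Minimizes tr(S Theta) - log det Theta + rho ||Theta||_1 over ALL
    entries (the positive diagonal makes its l1 term linear, matching
    the w_ii = s_ii + rho convention of the blockwise algorithm).
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    Z = np.eye(p)
    U = np.zeros((p, p))
    for _ in range(max_iter):
        lam, Qe = np.linalg.eigh(t * (Z - U) - S)
        theta_eigs = (lam + np.sqrt(lam**2 + 4.0 * t)) / (2.0 * t)
        Theta = (Qe * theta_eigs) @ Qe.T
        Z_old = Z
        A = Theta + U
        Z = np.sign(A) * np.maximum(np.abs(A) - rho / t, 0.0)
        U = U + Theta - Z
        primal = np.abs(Theta - Z).max()
        dual = t * np.abs(Z - Z_old).max()
        if primal < tol and dual < tol:
            break
    return Z


def glasso_objective(theta, S, rho):
    """tr(S Theta) - log det Theta + rho ||Theta||_1 (all entries)."""
    sign, logdet = np.linalg.slogdet(theta)
    assert sign > 0
    return float(np.trace(S @ theta) - logdet + rho * np.abs(theta).sum())
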