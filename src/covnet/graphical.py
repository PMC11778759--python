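"""Step 2: sparse precision estimation on the residuals and thresholding.

The empirical covariance S of the residual matrix is fed to the
graphical lasso, which maximizes

    log det Theta - tr(S Theta) - rho ||Theta||_1

by blockwise coordinate descent (the off-diagonal entries carry the l1
penalty; the diagonal enters only through the W = S + rho I convention,
so w_ii = s_ii + rho exactly).  The penalty rho is chosen on a fixed
grid by the extended BIC, partial correlations are read off the chosen
precision matrix as r_ij = -theta_ij / sqrt(theta_ii theta_jj), and the
network keeps the pairs whose |r| reaches a percentile threshold.
"""

from __future__ import annotations

import warnings

import numpy as np

from ._solvers import _glasso_sweeps
from .datatypes import EBICSelection, Network, PrecisionEstimate
from .exceptions import ConvergenceError

__all__ = [
    "empirical_covariance",
    "graphical_lasso",
    "constrained_mle",
    "ebic_score",
    "select_rho",
    "partial_correlations",
    "threshold_network",
    "DEFAULT_RHO_GRID",
]

DEFAULT_RHO_GRID = tuple(round(0.1 * k, 1) for k in range(1, 10))
EDGE_TOL = 1e-8  # |theta_ij| above this counts as an edge


def empirical_covariance(E) -> np.ndarray:
    """S = (1/n) Ec' Ec with column-centered residuals (denominator n)."""
    E = np.asarray(E, dtype=float)
    if E.ndim != 2 or E.shape[0] < 2:
        raise ValueError("residual matrix needs at least 2 rows")
    Ec = E - E.mean(axis=0)
    return Ec.T @ Ec / E.shape[0]


def _check_cov(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("covariance must be square")
    if np.abs(S - S.T).max() > 1e-8:
        raise ValueError("covariance must be symmetric")
    return (S + S.T) / 2.0


def graphical_lasso(S, rho: float, tol: float = 1e-4,
                    max_iter: int = 200) -> PrecisionEstimate:
    """l1-penalized precision estimation by blockwise coordinate descent.

    W is initialized to S + rho I and each column's off-diagonal block is
    updated as the solution of a lasso subproblem; sweeps stop when the
    mean absolute change of the off-diagonal entries of W falls below
    ``tol`` times the mean absolute off-diagonal of S.  Theta is
    recovered from the final W and the subproblem coefficients.
    """
    S = _check_cov(S)
    if rho < 0:
        raise ValueError("rho must be nonnegative")
    p = S.shape[0]
    if rho == 0 and np.linalg.matrix_rank(S) < p:
        raise ValueError("S is singular at rho = 0; use rho > 0")
    W = S.copy()
    W[np.diag_indices(p)] += rho
    B = np.zeros((p, p))
    offdiag_scale = float(np.abs(S - np.diag(np.diag(S))).sum()) / max(p * (p - 1), 1)
    if offdiag_scale == 0.0:
        # decoupled problems: W stays diagonal, beta = 0
        theta = np.diag(1.0 / np.diag(W))
        return PrecisionEstimate(theta=theta, w=W, rho=float(rho),
                                 converged=True, iterations=0)
    tol_w = tol * offdiag_scale
    iters = _glasso_sweeps(S, W, B, float(rho), float(tol_w), 1e-9,
                           int(max_iter), 10_000)
    if iters < 0:
        raise ConvergenceError(
            f"graphical lasso did not converge within {max_iter} sweeps (rho={rho})"
        )
    theta = np.empty((p, p))
    for j in range(p):
        mask = np.arange(p) != j
        beta = B[mask, j]
        theta_jj = 1.0 / (W[j, j] - float(W[mask, j] @ beta))
        theta[j, j] = theta_jj
        theta[mask, j] = -beta * theta_jj
    theta = (theta + theta.T) / 2.0
    return PrecisionEstimate(theta=theta, w=W, rho=float(rho),
                             converged=True, iterations=int(iters))


def support_matrix(theta: np.ndarray, tol: float = EDGE_TOL) -> np.ndarray:
    """Boolean off-diagonal support of a precision matrix."""
    A = np.abs(theta) > tol
    np.fill_diagonal(A, False)
    return A


def constrained_mle(S: np.ndarray, support: np.ndarray, tol: float = 1e-8,
                    max_iter: int = 500) -> np.ndarray:
    """Gaussian MLE of the precision matrix restricted to a given support.

    Classic blockwise "modified regression" algorithm for covariance
    selection: per column, the allowed off-diagonal entries solve an
    unpenalized regression in W, forbidden ones are pinned at zero.  Used
    to score candidate supports with eBIC on an even footing.
    """
    S = _check_cov(S)
    p = S.shape[0]
    W = S.copy()
    B = np.zeros((p, p))
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            mask = np.arange(p) != j
            active = support[mask, j]
            W11 = W[np.ix_(mask, mask)]
            beta = np.zeros(p - 1)
            if active.any():
                Wa = W11[np.ix_(active, active)]
                beta[active] = np.linalg.solve(Wa, S[mask, j][active])
            w12 = W11 @ beta
            delta += float(np.abs(w12 - W[mask, j]).mean())
            W[mask, j] = w12
            W[j, mask] = w12
            B[mask, j] = beta
        if delta / p < tol:
            break
    theta = np.empty((p, p))
    for j in range(p):
        mask = np.arange(p) != j
        beta = B[mask, j]
        theta_jj = 1.0 / (W[j, j] - float(W[mask, j] @ beta))
        theta[j, j] = theta_jj
        theta[mask, j] = -beta * theta_jj
    return (theta + theta.T) / 2.0


def ebic_score(theta, S, n: int, gamma: float) -> float:
    """Extended BIC of a precision matrix against a covariance.

    -n [log det Theta - tr(S Theta)] + k log n + 4 k gamma log p, where k
    counts nonzero off-diagonal pairs once.  gamma = 0 recovers the plain
    BIC; larger gamma penalizes dense graphs more, which is the p >> n
    regime correction.
    """
    theta = np.asarray(theta, dtype=float)
    S = np.asarray(S, dtype=float)
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0 or np.linalg.eigvalsh(theta).min() <= 0:
        raise ValueError("theta must be positive definite")
    p = theta.shape[0]
    k = int(support_matrix(theta).sum()) // 2
    loglik_term = logdet - float(np.trace(S @ theta))
    return float(-n * loglik_term + k * np.log(n) + 4.0 * k * gamma * np.log(p))


def select_rho(S, n: int, rho_grid=DEFAULT_RHO_GRID, gamma: float = 0.5, *,
               refit: bool = True, tol: float = 1e-4, max_iter: int = 200):
    """Pick rho on a grid by minimizing eBIC; ties go to the larger rho.

    By default each candidate support is refitted to its support-
    constrained MLE before scoring, so that two penalties yielding the
    same graph score identically (the likelihood is then a function of
    the support alone) and the sparser-penalty tie-break applies.  With
    ``refit=False`` the penalized estimate itself is scored.

    Returns ``(EBICSelection, PrecisionEstimate)`` for the winning rho.
    """
    grid = [float(r) for r in rho_grid]
    if not grid:
        raise ValueError("rho grid is empty")
    S = _check_cov(S)
    estimates: dict[float, PrecisionEstimate] = {}
    scores: dict[float, float] = {}
    for rho in grid:
        try:
            est = graphical_lasso(S, rho, tol=tol, max_iter=max_iter)
            theta_for_score = est.theta
            if refit:
                try:
                    theta_for_score = constrained_mle(S, support_matrix(est.theta))
                except np.linalg.LinAlgError:
                    theta_for_score = est.theta
            scores[rho] = ebic_score(theta_for_score, S, n, gamma)
            estimates[rho] = est
        except (ConvergenceError, ValueError) as err:
            warnings.warn(f"rho={rho} skipped: {err}", stacklevel=2)
    if not estimates:
        raise ConvergenceError("graphical lasso failed on every rho in the grid")
    best = min(scores.values())
    tie_tol = 1e-9 * max(1.0, abs(best))
    chosen = max(r for r, v in scores.items() if v <= best + tie_tol)
    selection = EBICSelection(
        rho_grid=[r for r in grid if r in scores],
        ebic_values=[scores[r] for r in grid if r in scores],
        gamma=float(gamma),
        chosen_rho=chosen,
        n_effective=int(n),
    )
    return selection, estimates[chosen]


def partial_correlations(theta) -> np.ndarray:
    """r_ij = -theta_ij / sqrt(theta_ii theta_jj), zero diagonal."""
    theta = np.asarray(theta, dtype=float)
    d = np.diag(theta)
    if (d <= 0).any():
        raise ValueError("theta diagonal must be positive")
    denom = np.sqrt(np.outer(d, d))
    r = -theta / denom
    np.fill_diagonal(r, 0.0)
    return (r + r.T) / 2.0


def threshold_network(r, percentile: float, gene_ids: list[str], *,
                      rho: float | None = None,
                      zero_tol: float = EDGE_TOL) -> Network:
    """Keep the pairs whose |partial correlation| reaches a percentile.

    The threshold is the empirical percentile (linear interpolation) of
    the nonzero |r_ij| over unordered pairs; exact zeros produced by the
    graphical lasso are excluded from the pool, otherwise a sparse
    solution would make high percentiles trivially zero.  An all-zero
    matrix yields an empty network with threshold 0.  percentile = 0
    degenerates to keeping every nonzero pair.
    """
    if not 0 <= percentile < 100:
        raise ValueError("percentile must be in [0, 100)")
    r = np.asarray(r, dtype=float)
    p = r.shape[0]
    iu = np.triu_indices(p, k=1)
    vals = np.abs(r[iu])
    nonzero = vals > zero_tol
    if not nonzero.any():
        return Network(gene_ids=gene_ids, weights=r,
                       adjacency=np.zeros((p, p), dtype=int),
                       threshold_value=0.0, rho=rho)
    threshold = float(np.percentile(vals[nonzero], percentile))
    adj = ((np.abs(r) >= threshold) & (np.abs(r) > zero_tol)).astype(int)
    np.fill_diagonal(adj, 0)
    return Network(gene_ids=gene_ids, weights=r, adjacency=adj,
                   threshold_value=threshold, rho=rho)
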