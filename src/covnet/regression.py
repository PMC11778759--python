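"""Step 1: covariate adjustment by penalized cross-species regression.

The target species' expression matrix Y (n x p) is regressed, gene by
gene, on the auxiliary species' matrix X (n x q) under an elastic-net
penalty, after standardization and bootstrap augmentation of the jointly
resampled rows.  The per-response penalty lambda_j is chosen by K-fold
cross-validation (lambda.min by default, one-standard-error rule
optionally).  The object of interest is the residual matrix
E = Y_aug - [1 X_aug] B_hat, which feeds the graphical-lasso step.

The fitted objective for response y is

    (1/(2n)) ||y - b0 - X b||^2 + lam * [ (1-alpha)/2 ||b||^2 + alpha ||b||_1 ]

with the intercept b0 unpenalized.  The 1/(2n) scaling makes lambda
values comparable across sample sizes (the augmented data have many more
rows than the originals).
"""

from __future__ import annotations

import math
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from ._rng import substream, subseed
from ._solvers import _cd_gram
from .datatypes import (
    AugmentedData,
    CVResult,
    ExpressionMatrix,
    PenaltySpec,
    RegressionFit,
)
from .exceptions import ConvergenceError, FormatError

__all__ = [
    "standardize",
    "bootstrap_augment",
    "fit_penalized_response",
    "lambda_max",
    "auto_lambda_grid",
    "cross_validate_lambda",
    "fit_multiresponse",
    "select_best_covariate",
    "select_from_mse_table",
    "BestCovariate",
]

DEFAULT_TOL = 1e-7
DEFAULT_MAX_ITER = 100_000
_ALPHA_LABELS = {1.0: "lasso", 0.0: "ridge"}


def _as_values(M) -> np.ndarray:
    if isinstance(M, ExpressionMatrix):
        return M.values
    return np.asarray(M, dtype=float)


def standardize(M, names: Sequence[str] | None = None):
    """Center and scale columns to mean 0, sd 1 (denominator n-1).

    Returns ``(Z, centers, scales)``; a zero-variance column is an error
    naming the offending column.
    """
    V = _as_values(M)
    if isinstance(M, ExpressionMatrix) and names is None:
        names = M.gene_ids
    centers = V.mean(axis=0)
    scales = V.std(axis=0, ddof=1)
    bad = np.nonzero(scales == 0)[0]
    if bad.size:
        label = names[bad[0]] if names is not None else f"column {bad[0]}"
        raise ValueError(f"zero-variance column: {label}")
    return (V - centers) / scales, centers, scales


def bootstrap_augment(X, Y, n_boot: int, sigma2: float, seed: int) -> AugmentedData:
    """Resample rows jointly with replacement and add Gaussian jitter.

    Each augmented row k copies source row idx_k of BOTH X and Y (the same
    index, so the cross-species pairing survives) and then receives
    independent N(0, sigma2 I) jitter, drawn separately for the X part and
    the Y part.  sigma2 = 0 reproduces plain bootstrap rows exactly.
    """
    Xv, Yv = _as_values(X), _as_values(Y)
    if Xv.shape[0] != Yv.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    rng = substream(seed, "bootstrap")
    idx = rng.integers(0, Xv.shape[0], size=n_boot)
    sd = math.sqrt(sigma2)
    X_aug = Xv[idx] + rng.normal(0.0, 1.0, size=(n_boot, Xv.shape[1])) * sd
    Y_aug = Yv[idx] + rng.normal(0.0, 1.0, size=(n_boot, Yv.shape[1])) * sd
    return AugmentedData(
        X_aug=X_aug, Y_aug=Y_aug, n_boot=n_boot, sigma2=sigma2, seed=seed,
        source_rows=idx,
    )


def _check_design(X: np.ndarray) -> np.ndarray:
    """Penalization mask: the leading all-ones column, if present, is free."""
    penalized = np.ones(X.shape[1], dtype=bool)
    if np.all(X[:, 0] == 1.0):
        penalized[0] = False
    return penalized


def _cd_solve(G, c, alpha, lam, penalized, b0=None, tol=DEFAULT_TOL,
              max_iter=DEFAULT_MAX_ITER, context=""):
    b = np.zeros(G.shape[0]) if b0 is None else b0.copy()
    iters = _cd_gram(G, c, b, penalized, float(alpha), float(lam), float(tol),
                     int(max_iter))
    if iters < 0:
        raise ConvergenceError(
            f"coordinate descent did not converge in {max_iter} sweeps{context}"
        )
    return b


def fit_penalized_response(X, y, alpha: float, lam: float, *, tol: float = DEFAULT_TOL,
                           max_iter: int = DEFAULT_MAX_ITER) -> np.ndarray:
    """Solve one penalized response by cyclic coordinate descent.

    ``X`` carries the intercept as its first (all-ones, unpenalized)
    column.  ``lam = 0`` recovers ordinary least squares; for alpha = 1
    and ``lam >= max_j |x_j'(y - ybar)| / n`` every non-intercept
    coefficient is exactly zero.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite entries in regression inputs")
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    n = X.shape[0]
    G = X.T @ X / n
    c = X.T @ y / n
    return _cd_solve(G, c, alpha, lam, _check_design(X), tol=tol, max_iter=max_iter)


def lambda_max(X, y, alpha: float) -> float:
    """Smallest penalty that zeroes all non-intercept coefficients (lasso);
    for alpha < 1 the conventional max(alpha, 1e-3) rescaling is applied."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    penalized = _check_design(X)
    yc = y - y.mean() if not penalized[0] else y
    n = X.shape[0]
    lm = np.abs(X[:, penalized].T @ yc / n).max()
    return float(lm / max(alpha, 1e-3))


def auto_lambda_grid(X, y, alpha: float, n_lambda: int = 100,
                     eps: float = 1e-3) -> np.ndarray:
    """Standard pathwise grid: n_lambda log-spaced values from lambda_max
    down to eps * lambda_max, descending."""
    lm = lambda_max(X, y, alpha)
    if lm <= 0:
        lm = 1.0
    return np.geomspace(lm, eps * lm, n_lambda)


def cv_folds(n: int, Q: int, seed: int) -> list[np.ndarray]:
    """Deterministic partition of n rows into Q near-equal blocks."""
    perm = substream(seed, "cv-folds").permutation(n)
    return [np.sort(block) for block in np.array_split(perm, Q)]


def cross_validate_lambda(X, y, alpha: float, Q: int, lambda_grid, seed: int, *,
                          warm_start: bool = False, tol: float = DEFAULT_TOL,
                          max_iter: int = DEFAULT_MAX_ITER) -> CVResult:
    """Q-fold cross-validation of the penalty for one response.

    For each lambda on the (descending) grid the model is fitted on Q-1
    blocks and scored on the held-out block by per-observation RSS; the
    fold average is the MSE curve.  ``lambda_min`` minimizes the curve and
    ``lambda_1se`` is the largest lambda within one standard error of that
    minimum.  With ``warm_start`` the path is solved warm-started per fold
    (same optimum, fewer sweeps); the default re-solves each lambda from
    zeros so the curve matches a naive fold loop bit for bit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if Q < 2:
        raise ValueError("Q must be >= 2")
    n = X.shape[0]
    if n < Q:
        raise ValueError("need at least Q rows")
    if isinstance(lambda_grid, str) or lambda_grid is None:
        grid = auto_lambda_grid(X, y, alpha)
    else:
        grid = np.asarray(list(lambda_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid is empty")
    penalized = _check_design(X)
    folds = cv_folds(n, Q, seed)
    fold_mse = np.empty((Q, grid.size))
    for q, test_idx in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        Xtr, ytr = X[mask], y[mask]
        Xte, yte = X[test_idx], y[test_idx]
        ntr = Xtr.shape[0]
        G = Xtr.T @ Xtr / ntr
        c = Xtr.T @ ytr / ntr
        b = None
        for s, lam in enumerate(grid):
            b = _cd_solve(G, c, alpha, lam, penalized,
                          b0=b if warm_start else None,
                          tol=tol, max_iter=max_iter,
                          context=f" (fold {q}, lambda {lam:.4g})")
            resid = yte - Xte @ b
            fold_mse[q, s] = float(resid @ resid) / len(test_idx)
    mse = fold_mse.mean(axis=0)
    se = fold_mse.std(axis=0, ddof=1) / math.sqrt(Q)
    k_min = int(np.argmin(mse))
    lam_min = float(grid[k_min])
    cutoff = mse[k_min] + se[k_min]
    within = np.nonzero(mse <= cutoff)[0]
    lam_1se = float(grid[within].max())
    return CVResult(
        lambda_grid=[float(v) for v in grid],
        mse_per_lambda=[float(v) for v in mse],
        se_per_lambda=[float(v) for v in se],
        lambda_min=lam_min,
        lambda_1se=lam_1se,
        folds=Q,
    )


def _align_genes(X: ExpressionMatrix, Y: ExpressionMatrix) -> ExpressionMatrix:
    """Reorder X's genes to match Y's identifiers; refuse mismatched sets."""
    if X.gene_ids == Y.gene_ids:
        return X
    if set(X.gene_ids) != set(Y.gene_ids):
        missing = sorted(set(Y.gene_ids) ^ set(X.gene_ids))[:5]
        raise FormatError(
            f"covariate gene set does not match target gene set (e.g. {missing})"
        )
    order = [X.gene_ids.index(g) for g in Y.gene_ids]
    return ExpressionMatrix(X.values[:, order], X.sample_ids, list(Y.gene_ids))


def _with_intercept(M: np.ndarray) -> np.ndarray:
    return np.hstack([np.ones((M.shape[0], 1)), M])


def _grids_per_response(penalty: PenaltySpec, A: np.ndarray,
                        Y: np.ndarray) -> list[np.ndarray]:
    if isinstance(penalty.lambda_grid, str):
        return [auto_lambda_grid(A, Y[:, j], penalty.alpha)
                for j in range(Y.shape[1])]
    grid = np.asarray(penalty.lambda_grid, dtype=float)
    return [grid] * Y.shape[1]


def _cv_original_rows(Xs, Ys, penalty, Q, n_boot, sigma2, seed, grids,
                      tol, max_iter):
    """Per-response CV where folds partition ORIGINAL rows.

    Each fold's training rows are bootstrap-augmented afresh and the path
    is scored on the truly held-out original rows, so duplicated rows
    never leak across the fold boundary.  Returns (fold_mse, folds) with
    fold_mse of shape (p, Q, n_lambda).
    """
    n = Xs.shape[0]
    p = Ys.shape[1]
    folds = cv_folds(n, Q, subseed(seed, "cv"))
    n_lambda = len(grids[0])
    fold_mse = np.empty((p, Q, n_lambda))
    penalized = None
    for qi, test_idx in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        aug = bootstrap_augment(Xs[mask], Ys[mask], n_boot, sigma2,
                                subseed(seed, "cv-augment", qi))
        A_tr = _with_intercept(aug.X_aug)
        A_te = _with_intercept(Xs[test_idx])
        if penalized is None:
            penalized = _check_design(A_tr)
        ntr = A_tr.shape[0]
        G = A_tr.T @ A_tr / ntr
        for j in range(p):
            yj = aug.Y_aug[:, j]
            c = A_tr.T @ yj / ntr
            b = None
            yte = Ys[test_idx, j]
            for s, lam in enumerate(grids[j]):
                b = _cd_solve(G, c, penalty.alpha, lam, penalized, b0=b,
                              tol=tol, max_iter=max_iter,
                              context=f" (response {j}, fold {qi})")
                resid = yte - A_te @ b
                fold_mse[j, qi, s] = float(resid @ resid) / len(test_idx)
    return fold_mse, folds


def fit_multiresponse(X, Y, penalty: PenaltySpec | None = None, Q: int = 10,
                      n_boot: int = 1000, sigma2: float = 0.001, seed: int = 0, *,
                      cv_on: str = "original",
                      test_fraction: float | None = None,
                      keep_cv: bool = False,
                      tol: float = DEFAULT_TOL,
                      max_iter: int = DEFAULT_MAX_ITER) -> RegressionFit:
    """Fit all p penalized responses and return the residual matrix.

    Pipeline: standardize X and Y column-wise on the original rows, hold
    out a test split for the reported ``mse_test``, cross-validate
    lambda per response, refit at the selected lambda on the bootstrap-
    augmented training rows, and assemble B_hat ((q+1) x p) plus the
    residual matrix E = Y_aug - [1 X_aug] B_hat over the augmented rows.

    ``cv_on`` controls where the CV folds live:

    * ``"original"`` (default): folds partition the original rows and
      each fold's training block is bootstrap-augmented afresh, so the
      held-out rows are never duplicated into the training side.  The
      test split holds out original rows.
    * ``"augmented"``: one augmentation up front, folds partition the
      augmented rows.  Bootstrap copies of the same source row then
      appear on both sides of each fold boundary, which biases the CV
      error optimistically and drags lambda towards zero; kept because
      it is the obvious reading of augment-then-cross-validate.
    """
    penalty = penalty or PenaltySpec()
    if cv_on not in ("original", "augmented"):
        raise ValueError("cv_on must be 'original' or 'augmented'")
    Xv0, Yv0 = _as_values(X), _as_values(Y)
    if Xv0.shape[0] != Yv0.shape[0]:
        raise ValueError("X and Y must be row-aligned (same samples)")
    if (isinstance(X, ExpressionMatrix) and isinstance(Y, ExpressionMatrix)
            and X.sample_ids != Y.sample_ids):
        raise ValueError("X and Y sample identifiers disagree")
    x_names = X.gene_ids if isinstance(X, ExpressionMatrix) else None
    y_names = Y.gene_ids if isinstance(Y, ExpressionMatrix) else None
    Xs, cx, sx = standardize(Xv0, x_names)
    Ys, cy, sy = standardize(Yv0, y_names)
    p = Ys.shape[1]
    q = Xs.shape[1]
    cv_keep: list[CVResult] | None = [] if keep_cv else None

    if cv_on == "original":
        n = Xs.shape[0]
        frac = (1.0 / Q) if test_fraction is None else test_fraction
        n_test = max(1, int(round(n * frac)))
        if n - n_test < Q:
            raise ValueError("too few original rows for the requested folds")
        perm = substream(seed, "test-split").permutation(n)
        test_idx = np.sort(perm[:n_test])
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        Xtr, Ytr = Xs[train_mask], Ys[train_mask]
        aug = bootstrap_augment(Xtr, Ytr, n_boot, sigma2, subseed(seed, "augment"))
        A = _with_intercept(aug.X_aug)
        grids = _grids_per_response(penalty, A, aug.Y_aug)
        fold_mse, _ = _cv_original_rows(Xtr, Ytr, penalty, Q, n_boot, sigma2,
                                        seed, grids, tol, max_iter)
        A_te = _with_intercept(Xs[test_idx])
        Y_te = Ys[test_idx]
        Y_fit = aug.Y_aug
    else:
        aug = bootstrap_augment(Xs, Ys, n_boot, sigma2, subseed(seed, "augment"))
        n_aug = aug.X_aug.shape[0]
        frac = (1.0 / Q) if test_fraction is None else test_fraction
        n_test = max(1, int(round(n_aug * frac)))
        perm = substream(seed, "test-split").permutation(n_aug)
        test_idx = np.sort(perm[:n_test])
        train_mask = np.ones(n_aug, dtype=bool)
        train_mask[test_idx] = False
        A_full = _with_intercept(aug.X_aug)
        A = A_full[train_mask]
        A_te = A_full[test_idx]
        Y_te = aug.Y_aug[test_idx]
        Y_fit = aug.Y_aug[train_mask]
        grids = _grids_per_response(penalty, A, Y_fit)
        fold_seed = subseed(seed, "cv")
        fold_mse = None  # computed via cross_validate_lambda below

    ntr = A.shape[0]
    penalized = _check_design(A)
    G = A.T @ A / ntr
    B = np.empty((q + 1, p))
    chosen = []
    for j in range(p):
        try:
            if cv_on == "original":
                mse = fold_mse[j].mean(axis=0)
                se = fold_mse[j].std(axis=0, ddof=1) / math.sqrt(Q)
                k_min = int(np.argmin(mse))
                cutoff = mse[k_min] + se[k_min]
                lam_min = float(grids[j][k_min])
                lam_1se = float(grids[j][np.nonzero(mse <= cutoff)[0]].max())
                cv = CVResult(
                    lambda_grid=[float(v) for v in grids[j]],
                    mse_per_lambda=[float(v) for v in mse],
                    se_per_lambda=[float(v) for v in se],
                    lambda_min=lam_min, lambda_1se=lam_1se, folds=Q,
                )
            else:
                cv = cross_validate_lambda(
                    A, Y_fit[:, j], penalty.alpha, Q, grids[j], fold_seed,
                    warm_start=True, tol=tol, max_iter=max_iter,
                )
            lam = cv.lambda_min if penalty.lambda_rule == "min" else cv.lambda_1se
            c = A.T @ Y_fit[:, j] / ntr
            B[:, j] = _cd_solve(G, c, penalty.alpha, lam, penalized,
                                tol=tol, max_iter=max_iter)
        except ConvergenceError as err:
            raise ConvergenceError(f"response {j}: {err}") from err
        chosen.append(float(lam))
        if cv_keep is not None:
            cv_keep.append(cv)
    residuals = aug.Y_aug - _with_intercept(aug.X_aug) @ B
    mse_test = float(np.mean((Y_te - A_te @ B) ** 2))
    return RegressionFit(
        coefficients=B, chosen_lambda=chosen, alpha=penalty.alpha,
        residuals=residuals, mse_test=mse_test, lambda_rule=penalty.lambda_rule,
        cv_results=cv_keep, centers_x=cx, scales_x=sx, centers_y=cy, scales_y=sy,
    )


class BestCovariate(NamedTuple):
    species: str
    alpha: float
    fit: RegressionFit
    mse_table: dict[tuple[str, float], float]
    tie: bool


def select_from_mse_table(mse_table: Mapping[tuple[str, float], float],
                          alphas: Sequence[float]) -> tuple[str, float, bool]:
    """Pick the (species, alpha) pair with the minimum test MSE.

    Ties are broken by the listed alpha order first, then lexicographic
    species name; a tie on the minimum value is flagged.
    """
    if not mse_table:
        raise ValueError("empty MSE table")
    alpha_rank = {a: i for i, a in enumerate(alphas)}

    def rank(item):
        (species, alpha), mse = item
        return (mse, alpha_rank.get(alpha, len(alphas)), species)

    best = min(mse_table.items(), key=rank)
    best_value = best[1]
    tie = sum(1 for v in mse_table.values() if v == best_value) > 1
    return best[0][0], best[0][1], tie


def select_best_covariate(candidates: Mapping[str, ExpressionMatrix],
                          Y: ExpressionMatrix,
                          alphas: Sequence[float] = (1.0, 0.0, 0.5),
                          Q: int = 10, n_boot: int = 1000, sigma2: float = 0.001,
                          seed: int = 0, *, lambda_rule: str = "min",
                          lambda_grid="auto") -> BestCovariate:
    """Fit every (auxiliary species, alpha) pair and keep the MSE winner.

    All fits share one derived seed so the bootstrap rows and the test
    split are paired across candidates.  ``alphas`` defaults to lasso,
    ridge and the midpoint elastic net.
    """
    if not candidates:
        raise ValueError("need at least one candidate covariate matrix")
    if not alphas:
        raise ValueError("need at least one alpha")
    fit_seed = subseed(seed, "covariate-selection")
    fits: dict[tuple[str, float], RegressionFit] = {}
    table: dict[tuple[str, float], float] = {}
    for name in candidates:
        Xc = _align_genes(candidates[name], Y) if isinstance(
            candidates[name], ExpressionMatrix) else candidates[name]
        for a in alphas:
            spec = PenaltySpec(alpha=a, lambda_grid=lambda_grid,
                               lambda_rule=lambda_rule)
            fit = fit_multiresponse(Xc, Y, spec, Q=Q, n_boot=n_boot,
                                    sigma2=sigma2, seed=fit_seed)
            fits[(name, a)] = fit
            table[(name, a)] = fit.mse_test
    species, alpha, tie = select_from_mse_table(table, alphas)
    return BestCovariate(species, alpha, fits[(species, alpha)], table, tie)


def penalty_label(alpha: float) -> str:
    """Human-readable name for an elastic-net mixing value."""
    return _ALPHA_LABELS.get(alpha, f"elastic-net({alpha:g})")
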