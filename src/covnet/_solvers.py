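"""Low-level coordinate-descent kernels (numba-accelerated when available).

The elastic-net objective solved here is

    (1/(2n)) ||y - X b||^2 + lam * [ (1-alpha)/2 ||b_-0||^2 + alpha ||b_-0||_1 ]

expressed in Gram form with G = X'X/n and c = X'y/n, so one coordinate
update costs O(q) regardless of n.  The cyclic update for a penalized
coordinate is the classic soft-threshold step

    b_j <- S(z_j, lam*alpha) / (G_jj + lam*(1-alpha)),   z_j = c_j - g_j'b + G_jj b_j

with S(z, t) = sign(z) * max(|z| - t, 0); unpenalized coordinates (the
intercept) use the plain least-squares update.  Convergence is declared
when the largest coefficient change in a full sweep drops below ``tol``.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(fastmath=False)
def _cd_gram(G, c, b, penalized, alpha, lam, tol, max_iter):
    """Cyclic coordinate descent on the Gram system; returns sweeps used.

    Mutates ``b`` in place.  A negative return value flags non-convergence.
    """
    q = G.shape[0]
    l1 = lam * alpha
    l2 = lam * (1.0 - alpha)
    # snap-to-zero guard: |z| within one part in 1e12 of the threshold is
    # treated as at the threshold, so lam >= lam_max yields exact zeros
    thr = l1 * (1.0 + 1e-12)
    for it in range(max_iter):
        dmax = 0.0
        for j in range(q):
            gjj = G[j, j]
            z = c[j] + gjj * b[j]
            for k in range(q):
                z -= G[j, k] * b[k]
            if penalized[j]:
                if z > thr:
                    bn = (z - l1) / (gjj + l2)
                elif z < -thr:
                    bn = (z + l1) / (gjj + l2)
                else:
                    bn = 0.0
            else:
                bn = z / gjj
            d = bn - b[j]
            if d != 0.0:
                if abs(d) > dmax:
                    dmax = abs(d)
                b[j] = bn
        if dmax < tol:
            return it + 1
    return -max_iter


@njit(fastmath=False)
def _glasso_sweeps(S, W, B, rho, tol_w, inner_tol, max_iter, inner_max_iter):
    """Blockwise coordinate descent for the graphical lasso.

    W starts at S + rho*I (caller's responsibility) and its diagonal is
    never touched.  Column j's off-diagonal block is the solution of the
    lasso subproblem  min_b  (1/2) b'W11 b - s12'b + rho ||b||_1 , solved
    by cyclic coordinate descent warm-started from B[:, j].  Returns the
    number of outer sweeps (negative if the sweep budget ran out).
    """
    p = S.shape[0]
    for it in range(max_iter):
        delta = 0.0
        noff = 0
        for j in range(p):
            # assemble W11 (without row/col j) implicitly via index maps
            for inner in range(inner_max_iter):
                dmax = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    z = S[k, j]
                    for m in range(p):
                        if m == j or m == k:
                            continue
                        z -= W[k, m] * B[m, j]
                    if z > rho:
                        bn = (z - rho) / W[k, k]
                    elif z < -rho:
                        bn = (z + rho) / W[k, k]
                    else:
                        bn = 0.0
                    d = bn - B[k, j]
                    if d != 0.0:
                        if abs(d) > dmax:
                            dmax = abs(d)
                        B[k, j] = bn
                if dmax < inner_tol:
                    break
            # w12 = W11 @ beta
            for k in range(p):
                if k == j:
                    continue
                acc = 0.0
                for m in range(p):
                    if m == j:
                        continue
                    acc += W[k, m] * B[m, j]
                delta += abs(acc - W[k, j])
                noff += 1
                W[k, j] = acc
                W[j, k] = acc
        if noff > 0 and delta / noff < tol_w:
            return it + 1
    return -max_iter
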