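"""Synthetic expression data with known network ground truth.

The generator mirrors the model the pipeline assumes: the auxiliary
species' expression X is exogenous noise, the target species' expression
is Y = [1 X] B + E with a sparse cross-species coefficient matrix B, and
the errors E are multivariate Gaussian with a sparse precision matrix
Omega.  The nonzero pattern of Omega is the gene-gene network the
pipeline is scored on; a nonzero B is exactly the confounding that makes
raw-Y network estimates pick up spurious edges.

Positive definiteness of Omega is enforced by diagonal dominance
(diag = 1 + sum_j |omega_ij|), which keeps the support exactly
controllable -- the quantity every downstream test cares about.
"""

from __future__ import annotations

import numpy as np

from ._rng import substream
from .datatypes import ExpressionMatrix, GoldStandard, GroundTruth, SimulationConfig

__all__ = [
    "generate_precision",
    "generate_dataset",
    "derive_gold_standard",
    "gene_labels",
]


def gene_labels(k: int, prefix: str = "g") -> list[str]:
    """Deterministic identifiers g0001, g0002, ..."""
    width = max(4, len(str(k)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(k)]


def generate_precision(p: int, edge_prob: float,
                       partial_corr_range: tuple[float, float] = (0.2, 0.4),
                       seed: int = 0) -> np.ndarray:
    """Sparse symmetric positive-definite precision matrix.

    Off-diagonal support is Erdos-Renyi with probability ``edge_prob``;
    nonzero entries get a random sign and a magnitude drawn uniformly
    from ``partial_corr_range``.  The diagonal is set to one plus the
    absolute row sum, which guarantees strict diagonal dominance and
    hence positive definiteness.
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError("edge_prob must be in [0, 1]")
    lo, hi = partial_corr_range
    if not 0 <= lo <= hi:
        raise ValueError("partial_corr_range must satisfy 0 <= low <= high")
    rng = substream(seed, "precision")
    omega = np.zeros((p, p))
    iu = np.triu_indices(p, k=1)
    present = rng.random(len(iu[0])) < edge_prob
    mags = rng.uniform(lo, hi, size=len(iu[0]))
    signs = rng.choice([-1.0, 1.0], size=len(iu[0]))
    vals = np.where(present, signs * mags, 0.0)
    omega[iu] = vals
    omega = omega + omega.T
    np.fill_diagonal(omega, 1.0 + np.abs(omega).sum(axis=1))
    min_eig = float(np.linalg.eigvalsh(omega).min())
    if min_eig <= 0:  # unreachable under diagonal dominance
        raise AssertionError(f"precision construction lost definiteness ({min_eig})")
    return omega


def precision_support(omega: np.ndarray, tol: float = 0.0) -> set[frozenset[int]]:
    """Unordered index pairs with a nonzero off-diagonal precision entry."""
    p = omega.shape[0]
    return {
        frozenset((i, j))
        for i in range(p)
        for j in range(i + 1, p)
        if abs(omega[i, j]) > tol
    }


def generate_dataset(cfg: SimulationConfig):
    """Draw (X, Y, truth) under Y = [1 X] B + E, E ~ N(0, Omega^-1).

    X is i.i.d. standard normal (n x q).  B has a zero intercept row and
    a fraction ``coef_sparsity`` of nonzero slope entries with magnitude
    ``coef_scale`` and random sign.  E rows are drawn via the Cholesky
    factor of Omega^-1.  Gene and sample identifiers are deterministic,
    and the whole draw is reproducible from ``cfg.seed``.
    """
    omega = generate_precision(cfg.p, cfg.edge_prob,
                               cfg.noise_partial_corr_range, cfg.seed)
    rng_b = substream(cfg.seed, "coefficients")
    B = np.zeros((cfg.q + 1, cfg.p))
    nz = rng_b.random((cfg.q, cfg.p)) < cfg.coef_sparsity
    signs = rng_b.choice([-1.0, 1.0], size=(cfg.q, cfg.p))
    B[1:] = np.where(nz, signs * cfg.coef_scale, 0.0)

    rng_x = substream(cfg.seed, "covariates")
    Xv = rng_x.normal(size=(cfg.n, cfg.q))

    sigma = np.linalg.inv(omega)
    L = np.linalg.cholesky(sigma)
    rng_e = substream(cfg.seed, "noise")
    E = rng_e.normal(size=(cfg.n, cfg.p)) @ L.T

    Yv = np.hstack([np.ones((cfg.n, 1)), Xv]) @ B + E

    samples = [f"s{i + 1:03d}" for i in range(cfg.n)]
    X = ExpressionMatrix(Xv, samples, gene_labels(cfg.q))
    Y = ExpressionMatrix(Yv, samples, gene_labels(cfg.p))
    truth = GroundTruth(precision=omega, coefficients=B,
                        support=precision_support(omega))
    return X, Y, truth


def derive_gold_standard(truth: GroundTruth, gene_ids: list[str],
                         tf_ids: list[str] | None = None) -> GoldStandard:
    """Turn the true precision support into a reference edge list.

    In symmetric mode (default) each unordered support pair {i, j} is
    emitted as both directed edges.  With ``tf_ids`` given, only pairs
    touching a designated TF are kept, directed TF -> target, which
    mimics a TF-by-target gold standard.
    """
    tf_set = set(tf_ids) if tf_ids is not None else None
    edges: set[tuple[str, str]] = set()
    for pair in truth.support:
        i, j = sorted(pair)
        a, b = gene_ids[i], gene_ids[j]
        if tf_set is None:
            edges.add((a, b))
            edges.add((b, a))
        else:
            if a in tf_set:
                edges.add((a, b))
            if b in tf_set:
                edges.add((b, a))
    tfs = sorted(tf_set) if tf_set is not None else list(gene_ids)
    return GoldStandard(tf_ids=tfs, edges=edges, gene_universe=list(gene_ids))
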