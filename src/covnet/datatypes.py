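"""Core value types shared across the pipeline.

These are deliberately plain dataclasses over numpy arrays / pandas-free
containers: every stage of the pipeline consumes and produces them, and
they carry just enough invariant checking to fail loudly at the boundary
where something went wrong rather than deep inside a solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import FormatError

__all__ = [
    "ExpressionMatrix",
    "GoldStandard",
    "Network",
    "GroundTruth",
    "SimulationConfig",
    "PenaltySpec",
    "CVResult",
    "AugmentedData",
    "RegressionFit",
    "PrecisionEstimate",
    "EBICSelection",
    "ConfusionCounts",
    "DiagnosticMeasures",
]


@dataclass
class ExpressionMatrix:
    """A samples x genes block of (log2) expression values.

    ``values`` is always oriented samples-by-genes; loaders transpose on
    the way in so downstream code never has to guess.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.gene_ids):
            raise FormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if n < 2 or p < 2:
            raise FormatError(f"need at least 2 samples and 2 genes, got {n} x {p}")
        dupes = _duplicates(self.gene_ids)
        if dupes:
            raise FormatError(f"duplicate gene identifiers: {sorted(dupes)}")
        if not np.isfinite(self.values).all():
            raise FormatError("expression matrix contains missing or non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class GoldStandard:
    """Directed TF -> target reference edges over a declared gene universe."""

    tf_ids: list[str]
    edges: set[tuple[str, str]]
    gene_universe: list[str]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        universe = set(self.gene_universe)
        for tf, target in self.edges:
            if tf == target:
                raise FormatError(f"self-edge ({tf}, {target}) in gold standard")
            if tf not in universe or target not in universe:
                raise FormatError(f"edge ({tf}, {target}) outside gene universe")
        if not set(self.tf_ids) <= universe:
            raise FormatError("tf_ids not contained in gene universe")


@dataclass
class Network:
    """Undirected weighted network over genes plus a thresholded adjacency.

    ``weights`` holds partial correlations (symmetric, zero diagonal);
    ``adjacency`` is the binary matrix after percentile thresholding.
    """

    gene_ids: list[str]
    weights: np.ndarray
    adjacency: np.ndarray
    threshold_value: float
    rho: float | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.adjacency = np.asarray(self.adjacency, dtype=int)
        p = len(self.gene_ids)
        if self.weights.shape != (p, p) or self.adjacency.shape != (p, p):
            raise FormatError("network matrices must be p x p over gene_ids")
        if np.abs(self.weights - self.weights.T).max() > 1e-10:
            raise FormatError("network weights must be symmetric")
        if np.diag(self.adjacency).any():
            raise FormatError("adjacency diagonal must be zero")

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, k=1).sum())

    def edge_list(self) -> list[tuple[str, str, float]]:
        """Retained edges as (gene_a, gene_b, weight), gene_a < gene_b."""
        out = []
        idx = np.argwhere(np.triu(self.adjacency, k=1))
        for i, j in idx:
            a, b = self.gene_ids[i], self.gene_ids[j]
            if b < a:
                a, b = b, a
            out.append((a, b, float(self.weights[i, j])))
        return sorted(out)


@dataclass
class GroundTruth:
    """Simulation ground truth: precision matrix, coefficients and support."""

    precision: np.ndarray
    coefficients: np.ndarray
    support: set[frozenset[int]]

    def __post_init__(self) -> None:
        self.precision = np.asarray(self.precision, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if np.linalg.eigvalsh(self.precision).min() <= 0:
            raise ValueError("ground-truth precision matrix is not positive definite")
        if not np.isfinite(self.coefficients).all():
            raise ValueError("ground-truth coefficients must be finite")


@dataclass
class SimulationConfig:
    """Knobs for the synthetic generator (defaults are the study conditions).

    The defaults emulate the few-samples / many-genes regime the method is
    designed for, scaled to desk size: n = 20 time points, p = q = 30 genes
    shared between the target and auxiliary species.
    """

    p: int = 30
    q: int = 30
    n: int = 20
    edge_prob: float = 0.1
    coef_sparsity: float = 0.1
    coef_scale: float = 1.0
    noise_partial_corr_range: tuple[float, float] = (0.2, 0.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 2 or self.n < 2 or self.q < 1:
            raise ValueError("need p >= 2, n >= 2, q >= 1")
        if not 0.0 <= self.edge_prob <= 1.0:
            raise ValueError("edge_prob must be in [0, 1]")
        if not 0.0 <= self.coef_sparsity <= 1.0:
            raise ValueError("coef_sparsity must be in [0, 1]")


@dataclass
class PenaltySpec:
    """Elastic-net penalty: alpha = 1 lasso, 0 ridge, in between elastic net."""

    alpha: float = 1.0
    lambda_grid: Sequence[float] | str = "auto"
    lambda_rule: str = "min"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError("lambda_rule must be 'min' or '1se'")
        if not isinstance(self.lambda_grid, str):
            grid = [float(v) for v in self.lambda_grid]
            if any(b >= a for a, b in zip(grid, grid[1:])):
                raise ValueError("lambda_grid must be strictly descending")
            if any(v < 0 for v in grid):
                raise ValueError("lambda values must be nonnegative")
            self.lambda_grid = grid
        elif self.lambda_grid != "auto":
            raise ValueError("lambda_grid must be a descending list or 'auto'")


@dataclass
class CVResult:
    """K-fold CV curve for one response with the two classic lambda rules."""

    lambda_grid: list[float]
    mse_per_lambda: list[float]
    se_per_lambda: list[float]
    lambda_min: float
    lambda_1se: float
    folds: int

    def __post_init__(self) -> None:
        if not (
            len(self.lambda_grid) == len(self.mse_per_lambda) == len(self.se_per_lambda)
        ):
            raise ValueError("CV curve length mismatch")
        if self.lambda_1se < self.lambda_min:
            raise ValueError("lambda_1se must be >= lambda_min")


@dataclass
class AugmentedData:
    """Jointly bootstrapped (X, Y) rows with small Gaussian jitter."""

    X_aug: np.ndarray
    Y_aug: np.ndarray
    n_boot: int
    sigma2: float
    seed: int
    source_rows: np.ndarray

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be nonnegative")
        if self.X_aug.shape[0] != self.n_boot or self.Y_aug.shape[0] != self.n_boot:
            raise ValueError("augmented row count mismatch")


@dataclass
class RegressionFit:
    """Per-response penalized fits assembled into one coefficient matrix.

    ``coefficients`` is (q+1) x p with row 0 the intercepts; ``residuals``
    is computed on the augmented data, so it has n_boot rows.
    """

    coefficients: np.ndarray
    chosen_lambda: list[float]
    alpha: float
    residuals: np.ndarray
    mse_test: float
    lambda_rule: str = "min"
    cv_results: list[CVResult] | None = None
    centers_x: np.ndarray | None = None
    scales_x: np.ndarray | None = None
    centers_y: np.ndarray | None = None
    scales_y: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.coefficients).all():
            raise ValueError("non-finite coefficients in regression fit")

    @property
    def intercepts(self) -> np.ndarray:
        return self.coefficients[0]

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coefficients[1:]))


@dataclass
class PrecisionEstimate:
    """Graphical-lasso output: precision theta and its covariance dual w."""

    theta: np.ndarray
    w: np.ndarray
    rho: float
    converged: bool
    iterations: int

    def __post_init__(self) -> None:
        if np.abs(self.theta - self.theta.T).max() > 1e-8:
            raise ValueError("precision estimate must be symmetric")
        if np.linalg.eigvalsh(self.theta).min() <= 0:
            raise ValueError("precision estimate must be positive definite")


@dataclass
class EBICSelection:
    """eBIC scores over the rho grid and the selected penalty."""

    rho_grid: list[float]
    ebic_values: list[float]
    gamma: float
    chosen_rho: float
    n_effective: int

    def __post_init__(self) -> None:
        if len(self.rho_grid) != len(self.ebic_values):
            raise ValueError("eBIC curve length mismatch")
        if self.chosen_rho not in self.rho_grid:
            raise ValueError("chosen_rho must come from the grid")


@dataclass
class ConfusionCounts:
    """TP/FP/FN/TN over a declared pair universe."""

    tp: int
    fp: int
    fn: int
    tn: int
    universe_size: int
    universe_mode: str

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.tp + self.fp + self.fn + self.tn != self.universe_size:
            raise ValueError("confusion counts must partition the universe")


@dataclass
class DiagnosticMeasures:
    """Precision / recall / accuracy / specificity at one operating point.

    ``degenerate`` names measures whose denominator was zero (reported as 0).
    """

    precision: float
    recall: float
    accuracy: float
    specificity: float
    degenerate: frozenset[str] = field(default_factory=frozenset)

    def as_dict(self) -> dict[str, float]:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "accuracy": self.accuracy,
            "specificity": self.specificity,
        }


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for it in items:
        if it in seen:
            dup.add(it)
        seen.add(it)
    return dup
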