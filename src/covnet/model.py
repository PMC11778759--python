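"""Model/results front end for the two-step network construction.

``CovariateAdjustedGRN`` is built from the target species' expression
matrix and one or more auxiliary candidate matrices; ``fit()`` runs the
whole procedure -- best-covariate selection by CV MSE, penalized
multi-response regression, graphical lasso on the residual covariance
with eBIC selection of rho, partial correlations, percentile threshold
-- and returns a ``CovariateAdjustedGRNResults`` holding every
intermediate estimate, with ``summary()`` and ``evaluate()`` hanging off
the results object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .datatypes import (
    ConfusionCounts,
    EBICSelection,
    ExpressionMatrix,
    GoldStandard,
    Network,
    PrecisionEstimate,
    RegressionFit,
)
from .evaluation import confusion_vs_gold, diagnostic_measures
from .graphical import (
    DEFAULT_RHO_GRID,
    empirical_covariance,
    partial_correlations,
    select_rho,
    threshold_network,
)
from .regression import BestCovariate, penalty_label, select_best_covariate

__all__ = ["CovariateAdjustedGRN", "CovariateAdjustedGRNResults"]


class CovariateAdjustedGRN:
    """Covariate-adjusted Gaussian graphical model of gene regulation.

    Parameters
    ----------
    endog
        Target species' expression (samples x genes).
    exog
        Either one auxiliary ``ExpressionMatrix`` or a mapping
        ``{species_name: ExpressionMatrix}`` of candidates; with several
        candidates the best (species, alpha) pair is chosen by test MSE.
    alphas
        Elastic-net mixing values to try (1 lasso, 0 ridge).
    folds, n_boot, sigma2
        CV fold count, bootstrap-augmentation size and jitter variance.
    rho_grid, gamma
        Graphical-lasso penalty grid and eBIC gamma.
    percentile
        Percentile of nonzero |partial correlation| kept as edges.
    """

    def __init__(self, endog: ExpressionMatrix,
                 exog: ExpressionMatrix | Mapping[str, ExpressionMatrix],
                 alphas: Sequence[float] = (1.0, 0.0, 0.5),
                 folds: int = 10, n_boot: int = 1000, sigma2: float = 0.001,
                 lambda_rule: str = "min", lambda_grid="auto",
                 rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
                 gamma: float = 0.5, percentile: float = 95.0,
                 scale_residuals: bool = True):
        self.endog = endog
        if isinstance(exog, ExpressionMatrix):
            exog = {"covariate": exog}
        self.candidates = dict(exog)
        self.alphas = list(alphas)
        self.folds = folds
        self.n_boot = n_boot
        self.sigma2 = sigma2
        self.lambda_rule = lambda_rule
        self.lambda_grid = lambda_grid
        self.rho_grid = list(rho_grid)
        self.gamma = gamma
        self.percentile = percentile
        self.scale_residuals = scale_residuals

    def fit(self, seed: int = 0) -> "CovariateAdjustedGRNResults":
        """Run both steps end to end, deterministically under ``seed``."""
        best = select_best_covariate(
            self.candidates, self.endog, self.alphas, Q=self.folds,
            n_boot=self.n_boot, sigma2=self.sigma2, seed=seed,
            lambda_rule=self.lambda_rule, lambda_grid=self.lambda_grid,
        )
        E = best.fit.residuals
        if self.scale_residuals:
            # glasso on the residual *correlation* matrix: the rho grid is
            # calibrated to unit scale, and partial correlations are
            # invariant to per-gene rescaling anyway
            E = E / E.std(axis=0, ddof=1)
        S = empirical_covariance(E)
        selection, precision = select_rho(
            S, n=best.fit.residuals.shape[0], rho_grid=self.rho_grid,
            gamma=self.gamma,
        )
        r = partial_correlations(precision.theta)
        network = threshold_network(r, self.percentile, self.endog.gene_ids,
                                    rho=selection.chosen_rho)
        return CovariateAdjustedGRNResults(
            model=self, seed=seed, selection=best, regression=best.fit,
            residual_covariance=S, ebic=selection, precision=precision,
            partial_corr=r, network=network,
        )


@dataclass
class CovariateAdjustedGRNResults:
    """Estimates and diagnostics from a fitted covariate-adjusted GRN."""

    model: CovariateAdjustedGRN
    seed: int
    selection: BestCovariate
    regression: RegressionFit
    residual_covariance: np.ndarray
    ebic: EBICSelection
    precision: PrecisionEstimate
    partial_corr: np.ndarray
    network: Network

    def network_at(self, percentile: float) -> Network:
        """Re-threshold the fitted partial correlations at another percentile."""
        return threshold_network(self.partial_corr, percentile,
                                 self.model.endog.gene_ids,
                                 rho=self.ebic.chosen_rho)

    def evaluate(self, gold: GoldStandard,
                 universe_mode: str = "tf_by_target") -> ConfusionCounts:
        return confusion_vs_gold(self.network, gold, universe_mode)

    def summary(self) -> str:
        """Plain-text summary in the spirit of a model-results table."""
        fit = self.regression
        lams = np.asarray(fit.chosen_lambda)
        lines = [
            "Covariate-adjusted GRN results",
            "=" * 46,
            f"target genes (p):          {self.model.endog.n_genes}",
            f"original samples (n):      {self.model.endog.n_samples}",
            f"bootstrap samples:         {fit.residuals.shape[0]}",
            f"jitter variance sigma^2:   {self.model.sigma2:g}",
            f"selected covariate:        {self.selection.species}",
            f"selected penalty:          {penalty_label(self.selection.alpha)}"
            + ("  [tie]" if self.selection.tie else ""),
            f"test MSE (selected):       {fit.mse_test:.5f}",
            f"lambda rule:               {fit.lambda_rule}",
            f"lambda_j median [range]:   {np.median(lams):.4g} "
            f"[{lams.min():.4g}, {lams.max():.4g}]",
            f"nonzero coefficients:      {fit.n_nonzero}",
            "-" * 46,
            f"glasso rho (eBIC, gamma={self.ebic.gamma:g}): {self.ebic.chosen_rho:g}",
            f"eBIC at chosen rho:        "
            f"{self.ebic.ebic_values[self.ebic.rho_grid.index(self.ebic.chosen_rho)]:.2f}",
            f"threshold percentile:      {self.model.percentile:g}",
            f"|partial corr| threshold:  {self.network.threshold_value:.4g}",
            f"edges retained:            {self.network.n_edges}",
        ]
        return "\n".join(lines)
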