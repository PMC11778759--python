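# Methods

`covnet` constructs a gene regulatory network (GRN) for one species by
combining two estimators: a penalized multi-response regression that
removes the part of the target species' expression explained by a
related species, and a graphical lasso that estimates a sparse Gaussian
graphical model on what is left.  This note records the model, the
numerical choices, and the limits of what the synthetic studies show.

## Model

Let Y (n × p) be the target species' expression over n samples and p
genes, and X (n × q) a related species' expression over the same
samples.  The working model is the multi-response Gaussian linear model

    Y = [1 X] B + E,        rows of E i.i.d.  N(0, Σ),   Ω = Σ⁻¹ sparse.

The GRN of interest is the off-diagonal support of the precision matrix
Ω: ω_ij ≠ 0 means genes i and j are conditionally dependent given all
other genes.  If the network were estimated from Y directly, shared
regulation inherited from the related species (B ≠ 0) would induce
marginal and partial correlations between target genes that have
nothing to do with their direct interactions; regressing Y on X first
and estimating the network from the residuals is precisely what removes
those spurious edges.

### Step 1 — covariate adjustment

Each gene j of Y is regressed on X under an elastic-net penalty,

    B̂_j = argmin_b (1/2n) ‖y_j − b₀ − X b‖² + λ_j [ (1−α)/2 ‖b‖² + α ‖b‖₁ ],

with α = 1 the lasso, α = 0 ridge, and the intercept unpenalized.  The
1/(2n) scaling keeps λ comparable across sample sizes.  The solver is
cyclic coordinate descent with the classic soft-threshold update
S(z, λα)/(v_j + λ(1−α)), where v_j is the j-th diagonal of XᵀX/n
(exactly 1 for standardized columns); convergence is declared when the
largest coefficient change in a sweep falls below `tol` (default 1e−7,
`max_iter` 1e5 sweeps).

Because expression studies have far fewer samples than genes, the data
are bootstrap-augmented before fitting: rows of (X, Y) are resampled
jointly with replacement up to `n_boot` rows (default 1000) and
perturbed with independent N(0, σ²I) jitter (default σ² = 0.001) so
that duplicated rows do not coincide exactly.

λ_j is chosen per response by Q-fold cross-validation (default Q = 10)
over a descending grid (default: 100 log-spaced values from
λ_max = max_j |x_jᵀ(y−ȳ)|/(n·max(α, 10⁻³)) down to 10⁻³ λ_max), with
either the minimum-MSE rule (default) or the one-standard-error rule.

**Where the CV folds live matters.**  If the folds partition the
*augmented* rows, bootstrap copies of the same source row appear on
both sides of every fold boundary; the CV error is then optimistic,
decreases monotonically as λ → 0, and — whenever q ≥ n — the selected
fit simply interpolates the original rows, leaving residuals that are
pure jitter and carry no network signal.  `covnet` therefore defaults
to `cv_on="original"`: the folds partition the original rows, each
fold's training block is bootstrap-augmented afresh, and the path is
scored on truly held-out original rows.  The naive variant is kept as
`cv_on="augmented"` for comparison.  The reported `mse_test` likewise
comes from a held-out split of original rows (fraction 1/Q).

When several candidate species (and several α values) are offered, the
model fits every (species, α) pair under one shared resampling plan and
keeps the pair with minimum test MSE; ties go to the earlier α in the
supplied list, then the lexicographically smaller species name.

### Step 2 — network inference

The residual matrix E (n_boot × p) is standardized per gene and its
empirical covariance S = (1/n) EᵀE (columns centered) is passed to the
graphical lasso,

    Θ̂ = argmax_Θ  log det Θ − tr(SΘ) − ρ ‖Θ‖₁,off ,

solved by blockwise coordinate descent: W is initialized to S + ρI and
each column's off-diagonal block solves a lasso subproblem; the
diagonal obeys w_ii = s_ii + ρ exactly.  Sweeps stop when the mean
absolute change of W's off-diagonals drops below `tol` (default 1e−4)
times the mean absolute off-diagonal of S.

Standardizing the residuals first makes S a correlation matrix.  This
is deliberate: the fixed penalty grid ρ ∈ {0.1, …, 0.9} presumes
unit-scale inputs, and the quantity thresholded downstream — the
partial correlation r_ij = −θ_ij/√(θ_ii θ_jj) — is invariant to
per-gene rescaling, so nothing of scientific interest is lost.  Raw
covariances remain available (`scale_residuals=False`).

ρ is selected on the grid by the extended BIC,

    eBIC_γ(Θ) = −n [log det Θ − tr(SΘ)] + k log n + 4 k γ log p ,

with k the number of off-diagonal nonzero pairs.  Two details:

* **Supports are scored, not shrunk estimates.**  By default each
  candidate support is refitted to its support-constrained Gaussian MLE
  (a blockwise modified-regression algorithm) before scoring.  This is
  the form in which the extended criterion is defined, and it makes the
  score a function of the support alone — two penalties producing the
  same graph score identically, and the tie goes to the larger
  (sparser) ρ.  Scoring the penalized estimate directly
  (`refit=False`) conflates shrinkage with model dimension.
* **γ and the effective sample size.**  The default γ = 0.5 targets
  the many-genes/few-samples regime the method exists for.  When
  p is small and n large — the regime of the desk-scale simulation
  studies — the extended term is deliberately conservative and plain
  BIC (γ = 0) is the calibrated criterion; the eBIC selection tests use
  γ = 0 for exactly that reason.  The n entering the criterion is by
  default the number of residual rows (the augmented count); because
  bootstrap rows are not independent this overstates the information,
  so it is exposed as `n_effective` rather than hidden.

The network keeps the gene pairs whose |partial correlation| reaches
the 95th percentile (configurable) of the *nonzero* |r_ij| — exact
zeros produced by the graphical lasso are excluded from the percentile
pool, otherwise any reasonably sparse solution would make high
percentiles trivially zero.  Thresholding uses absolute values:
negative partial correlations are real conditional dependencies.

### Evaluation

Inferred (undirected) networks are scored against a directed TF→target
gold standard over a declared pair universe.  The default
`tf_by_target` universe is every (TF, other-gene) ordered pair; a
predicted edge {a, b} claims (a, b) when a is a TF and (b, a) when b
is.  Predicted edges touching no TF fall outside the universe — with a
TF-only gold standard, counting unknown gene–gene biology as true
negatives would inflate accuracy.  `all_pairs` symmetrizes the gold
edges over all unordered pairs and is the natural mode for simulated
truth.  Precision, recall, accuracy and specificity follow the usual
confusion-matrix definitions; degenerate denominators return 0 and are
flagged rather than raised.

## Synthetic data

The generator draws exactly the working model: an Erdős–Rényi support
for Ω with off-diagonal magnitudes uniform in `noise_partial_corr_range`
and random signs, the diagonal set to 1 + Σ_j |ω_ij| (strict diagonal
dominance, hence guaranteed positive definiteness and exactly
controllable support); X i.i.d. standard normal; B with a
`coef_sparsity` fraction of ±`coef_scale` entries; E via the Cholesky
factor of Ω⁻¹.  One seed fans out into named substreams (precision,
coefficients, covariates, noise, bootstrap, folds, splits), so stages
are independently reproducible.

Defaults: p = q = 30 genes, n = 20 samples, edge probability 0.1,
partial-correlation magnitudes 0.2–0.4 (realized conditional
correlations ≈ 0.1–0.2 after diagonal dominance), coefficient sparsity
0.1 at magnitude 1.0.  These are a deliberately hard, realistic
regime: p ≥ n, weak edges, confounding comparable to the noise scale.

What the generator does *not* emulate: time-course autocorrelation
(samples are i.i.d., as the working model assumes), microarray noise
models, probe-level artifacts, or any mismatch between the two
species' gene sets.  Passing tests therefore show that the procedure
recovers conditional-dependence structure under its own assumptions —
not that those assumptions hold for real developmental time courses,
where dependent time points reduce the effective sample size further.

The replicated study behind `scripts/acceptance.py` (20 datasets at the
defaults, bootstrap size 500, lasso adjustment) compares the
covariate-adjusted network with a graphical lasso applied directly to
standardized Y at the same 95th-percentile threshold.  Support-recovery
F1 is low for both — at n = 20 with conditional correlations ≈ 0.15
no method recovers this network well, and the percentile threshold by
construction retains only the top 5% of nonzero partial correlations —
but the adjusted estimator is consistently better, which is the
method's claim: adjustment removes the cross-species confounding that
dominates the raw-expression estimate.

## Numerical choices and degenerate inputs

* Coordinate descent: tol 1e−7 (max coefficient change), 1e5 sweeps;
  a z-value within one part in 1e12 of the soft threshold snaps to
  zero so λ ≥ λ_max yields exact zeros.
* Graphical lasso: outer tol 1e−4 (relative, see above), 200 sweeps,
  inner lasso tol 1e−9; entries with |θ_ij| ≤ 1e−8 count as absent
  edges.  A diagonal S short-circuits to the closed form
  θ_ii = 1/(s_ii + ρ).  ρ = 0 with singular S is refused with advice
  to use ρ > 0.
* CV: each λ is solved cold by default, so the MSE curve is bit-for-bit
  reproducible by a naive fold loop; warm starts along the path are an
  internal speed option that changes results only below solver
  tolerance.
* Ties: λ ties resolve to the larger λ (first on the descending grid);
  ρ ties to the larger ρ; (species, α) ties by listed α order then
  species name, flagged in the output.
* Zero-variance genes are refused by name at standardization; duplicate
  gene identifiers and non-numeric cells are refused at load with a
  row/column report.  Gene matching across files is by identifier only.

## Known limitations

* The bootstrap-augmented residual covariance has at most n distinct
  rows of information; n_boot inflates the nominal but not the
  effective sample size, and the eBIC `n_effective` default inherits
  that optimism.
* The elastic-net penalty is used for the regression step only; the
  precision matrix is ℓ1-penalized (no elastic-net graphical
  estimator).
* No directionality: the inferred network is undirected, and the
  TF→target projection at evaluation time is a scoring convention, not
  an orientation method.
* Single operating point: the percentile threshold gives one network
  per fit; no ROC/PR sweeps are produced.
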