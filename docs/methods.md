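# Methods

## Model and solver

The package completes a partially observed cell line × drug response matrix
under two assumptions: the complete matrix is low rank, and its columns
depend approximately linearly on the cell lines' gene-expression profiles.
With M′ the column-standardized, zero-filled response matrix, Ω its observed
index set, and U the PCA score matrix of the centered expression matrix, the
estimator solves

    min_{M, Λ}  ½‖UΛ − M‖²_F + β‖M‖_* + δ_G(M),
    G = { M : ‖P_Ω(M − M′)‖_F ≤ ε },

a convex problem combining a least-squares pull toward the expression
subspace, the nuclear norm as rank surrogate, and a hard Frobenius noise
ball around the observed entries. Splitting M = N gives the ADMM iteration
(scaled dual Y = Γ/ρ):

1. Λ ← argmin ½‖UΛ − M‖²_F, solved from the normal equations
   (UᵀU)Λ = UᵀM by a Cholesky factorization of the k × k Gram matrix; the
   inverse is never formed, and a condition-number guard (>1e12) rejects
   degenerate component sets. The update uses the current M, i.e. Λ is
   refreshed before M in each sweep; the fixed point is the same if the
   order is swapped.
2. M ← prox_{β/(1+ρ)‖·‖_*}((UΛ + ρN − ρY)/(1+ρ)), the singular-value
   soft-threshold of the weighted average of the subspace fit and the
   dual-corrected feasible iterate.
3. N ← P_G(M + Y): unobserved coordinates pass through; the observed block
   is radially projected onto the ε-ball centered at the observed data.
   This is the exact minimizer of the N-subproblem, computed in closed form
   rather than by an inner projected-gradient loop — the same fixed point,
   one projection per sweep.
4. Y ← Y + M − N.

Initialization is M⁰ = N⁰ = M′, Y⁰ = 0, which is feasible for any ε ≥ 0 and
makes the solver fully deterministic. Convergence is declared when the
relative primal residual ‖M − N‖_F / max(1, ‖M′‖_F) falls below `tol`
(default 1e-6, default `max_iter` 500); the returned completion is the
feasible iterate N. A divergence guard aborts if the residual grows by more
than 1e6× its initial value and suggests a larger ρ.

### Ablation variants

* `no_pca` removes the UΛ data term. The M-subproblem then reduces to
  min β‖M‖_* + ρ/2‖M − N + Y‖²_F, whose minimizer is
  M = prox_{β/ρ‖·‖_*}(N − Y) (two lines of proximal algebra: the quadratic
  is centered at N − Y with weight ρ). No Λ is produced.
* `no_trace` forces β = 0; the M-update becomes the unthresholded average
  (UΛ + ρN − ρY)/(1+ρ), a least-squares fit within span(U) subject to the
  ball.

## Parameters

| parameter | default | meaning |
|---|---|---|
| β | 1e-2 | nuclear-norm weight; grid-searchable over {1e-4…1} |
| ρ | 1.0 | ADMM penalty; affects speed, not the fixed point |
| ε | 0.01·‖P_Ω(M′)‖_F | noise radius around observed entries (1% relative budget) |
| tol | 1e-6 | relative primal-residual stopping rule |
| max_iter | 500 | iteration cap |
| variance_target | 0.95 | PCA components retained (smallest k reaching the target, capped at min(rank, m−1) so UᵀU stays invertible) |

The (β, ρ) grid search hides a seeded, per-column-stratified 10% of the
observed entries, refits every grid point, and scores mean per-drug Pearson
correlation on the hidden slice; ties break toward smaller β then smaller
ρ, and the chosen configuration is reused unchanged across datasets and
folds.

## Normalization conventions

Column statistics are computed over observed entries only, with the sample
(k−1) standard deviation, and missing entries are set to 0 **after**
standardization — the zero fill then equals the observed-entry column mean,
a neutral value, instead of biasing columns with many missing entries. The
recorded per-column mean/sd state de-normalizes observed entries exactly
(round-trip tested to 1e-10). Both evaluation and solving happen on the
normalized scale; per-drug PCC/SCC are invariant to per-column positive
affine maps, so this convention cannot change reported correlations.
Accepted missing-value tokens are the empty cell, `NA`, and `NaN`
(case-insensitive). Response orientation is explicit metadata:
`higher_is_sensitive` for activity-area panels, `lower_is_sensitive` for
AUC/IC50 panels; downstream screening and fold changes consume the flag.

## PCA choices

Genes are centered but not variance-scaled before the SVD (expression
panels are already on a common log scale; a `scale_genes` flag exists).
U is the score matrix, not re-orthonormalized left singular vectors — the
solver's (UᵀU)⁻¹ would be the identity otherwise, and the two choices span
the same subspace. Component signs are fixed by making each loading
column's largest-magnitude entry positive, for reproducibility across
linear-algebra backends. Components with singular value below 1e-12·σ_max
are discarded.

## Cross-validation protocol

Fold units are observed entries, dealt per-column round-robin into folds
with a single global fold pointer, so each drug contributes near-equally to
every fold and global fold sizes differ by at most one. Entry-wise masking
is the standard matrix-completion protocol and matches the task of
predicting missing values (whole-cell-line extrapolation is out of scope:
the model interpolates only). Within each fold the training matrix is
re-normalized from training entries alone (leakage-tested), PCA is fit on
the never-masked expression once and shared, and predictions are collected
on the de-normalized scale. Per-drug correlations pool the predictions
across the folds of one repeat — the only scheme guaranteeing ≥2 points per
drug per statistic for sparsely observed drugs — then mean/sd are taken
across repeats. Undefined correlations (constant vectors) are excluded from
aggregates and counted, never coerced to 0. Failed folds are recorded in
the report, not silently dropped.

## Downstream statistics

* Mutant vs wild-type stratification uses the two-sided Wilcoxon rank-sum
  test: an exact null for combined n ≤ 25 with no ties, the
  tie-corrected normal approximation otherwise (Welch's t is available via
  `test="welch"` for sensitivity analysis). Rank-based testing is robust to
  the skewed response distributions typical of drug screens. Groups with
  fewer than 3 usable responses are flagged underpowered rather than
  tested.
* Fold change is the ratio of group mean *sensitivities*: the raw response
  when higher means sensitive, and the (max_observed − value) transform
  otherwise, so the ratio is positive and points in the sensitive
  direction; the transform is recorded on every report.
* Sensitivity screening reads "top 30% of observed values" in the
  sensitivity orientation: the threshold is the upper (1−q) observed
  quantile when higher means sensitive and the lower q quantile otherwise,
  with linear-interpolation quantiles. Only previously missing entries can
  be called.
* Drug–gene network edges require raw p < α (default 0.05) in **both** the
  observed and the completed data; Benjamini–Hochberg adjusted columns are
  attached for reference but do not gate inclusion. The edge set is
  monotone in α by construction.
* Gene ranking per drug defaults to model weights — the absolute gene-space
  weight |WΛ| obtained by back-projecting the fitted coefficients through
  the PCA loadings — with an expression/prediction correlation mode as the
  model-free alternative; ties break lexicographically by gene id, and an
  all-zero score column is flagged degenerate.
* Tissue summaries are arithmetic means of predicted responses per
  (tissue, drug) with cell-line counts; count-weighted tissue means
  recompose the overall column mean exactly.

## Synthetic generator

The generator emulates the structure the model assumes, with full ground
truth: expression is drawn from `k_true` latent factors plus isotropic
noise (sd 0.5); responses are U_true·Λ* with columns standardized, planted
directly on the normalized scale so normalization round-trips are tested
separately from recovery; `span_leak` moves a controlled variance fraction
orthogonal to the score span; masking hides a per-column quota
(⌊missing_fraction·m⌋), mirroring per-drug missingness patterns rather than
global MCAR; mutations are Bernoulli with planted location-only shifts of
`shift`·column-sd in the sensitive direction, with co-mutation shifts added
when both genes are mutant. Defaults (m=80, n=200, p=12, k_true=4, response
noise sd 0.1, 30% missing, no span leak, prevalence 0.3, 5 tissues) are
small enough to solve in milliseconds yet large enough for stable per-drug
correlations.

What the generator does **not** emulate: the marginal shapes of real panels
(activity-area skew, IC50 log-normality), dose–response measurement error
structure, batch effects, or correlated mutation co-occurrence. Passing
tests therefore demonstrate correctness of the algorithms under the model's
own assumptions, not expected performance on any real screen.

## Problem sizes and numerical notes

The test suite and the acceptance script use bundles between 40 and 100
cell lines, 50–300 genes, and 4–12 drugs: at these sizes every per-iteration
SVD is on an m × p matrix with p ≤ 12, so a full solve takes milliseconds
and the calibration studies (2000 null tests, 100-seed detection rates,
10-seed ablations) complete in seconds. Hidden-entry recovery is scored
against the generator's noiseless ground truth. One geometry subtlety: the
score span excludes the constant vector (scores are centered), so a
response column standardized on a *subsample* of rows carries a small
intercept outside the span; exact-recovery checks therefore construct the
observed matrix directly in the span, while correlation-based checks are
intercept-invariant and use the standard pipeline.

## Known limitations

* Interpolation only: new cell lines or new drugs (fully empty rows or
  columns) cannot be predicted.
* The ε-ball couples all observed entries through one global radius; a
  per-column radius might suit panels with heterogeneous noise.
* The exact hyperparameters behind published full-panel results are not
  recoverable; the grid search reproduces the selection *procedure*, not
  any specific published operating point.
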