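# Methods

This note records the model, the estimator and algorithmic choices, the
defaults and why they were chosen, and what the synthetic-data generator
does and does not emulate. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Marginal model and GEE estimation

Phenotype panels are modelled marginally: each occasion `y_it` follows an
exponential-family distribution with canonical link (logit for binomial,
identity for gaussian) and mean `g(μ_i) = X_i β + Z_i γ`. The working
covariance is `V_i = φ B_i^{1/2} R(α) B_i^{1/2}`. Because only canonical
links are supported, `∂μ_i/∂δ = B_i C_i` and the estimating equations take
the simple form `Σ C_iᵀ B_i V_i⁻¹ (y_i − μ_i) = 0`.

**Solver.** Fisher scoring: `δ ← δ + (Σ A_iᵀR⁻¹A_i)⁻¹ Σ A_iᵀR⁻¹ r_i` with
`A_i = B_i^{1/2} C_i` and `r_i` the Pearson residual vector (φ cancels from
the update). The fit is initialized at the independence solution (which for
t=1 *is* the IRLS GLM fit), then iterates coefficient updates with moment
re-estimation of (α, φ) until the max absolute coefficient change is below
1e-8, capped at 50 iterations per phase. Non-convergence is reported via a
flag; it is never silent.

**Moment estimators.** The model never states how φ and α should be
estimated, so the standard Pearson-residual moment estimators are used:
`φ̂ = Σ r² / (N_obs − q)` and, for exchangeable structure, the sum of
within-subject residual cross-products over (total pair count − q), divided
by φ̂ — the Liang–Zeger convention. α is clipped to
`[−1/(t−1)+1e−4, 1−1e−4]` so `R(α)` stays positive definite. For binomial
outcomes φ is **fixed at 1** by default (flag `estimate_phi` to override):
this is the binary-GEE convention and makes the classical-MDR reduction
exact. For gaussian outcomes φ is estimated.

**Missing occasions.** Subjects with partial occasions use the
corresponding sub-blocks of `R`; subjects are grouped by observation
pattern so the linear algebra stays vectorized. The default analysis rule
is complete-case (subjects missing any occasion or covariate are dropped at
the join), with a flag to keep partial-occasion subjects.

**Covariances.** Model-based `φ̂ (Σ AᵀR⁻¹A)⁻¹` and robust sandwich
`(ΣAᵀR⁻¹A)⁻¹ (Σ s_i s_iᵀ) (ΣAᵀR⁻¹A)⁻¹` with `s_i = A_iᵀR⁻¹r_i`. Joint
genetic-effect tests are Wald tests on the sandwich covariance with df =
number of genotype coefficients (t under the heterogeneous specification,
1 under homogeneous). The heterogeneous specification (one genotype
coefficient per occasion) is the screening default; the null model for
scoring excludes genotypes entirely, so scores are identical either way.

**Degenerate inputs.** A constant binary outcome or fitted probabilities
pinned to 0/1 (separation) raise a diagnostic error rather than returning a
meaningless fit. Exchangeable structure with t=1 is refused.

## Scores and the cell rule

The residual score vector is `S*_i = B̂_i V̂_i⁻¹ (y_i − μ̂_i)` computed under
the null fit, i.e. `φ̂⁻¹ B̂^{1/2} R⁻¹ r_i`; the prediction score is its
within-subject sum. Under independence the expression collapses to plain
residuals `(y−μ̂)/φ̂`, which the implementation computes directly so the
identity holds to the last bit. With an intercept in the null model the
scores sum to zero over subjects (the score-equation identity), which
centres the cell rule.

Cell labelling uses threshold `T₀ = 0` with a strict `>` ("greater than" is
strict; a cell sum of exactly zero is low-risk). A score-scaled tolerance
of `1e−12 · Σ|S_i|` guards the boundary: a sum that is zero up to
accumulated floating-point rounding must take the low branch, otherwise the
exact MDR reduction fails on tied cells. Cells unoccupied in training are
labelled *empty*; evaluation subjects landing in empty cells are treated as
low-risk by default (`empty_policy="exclude"` drops them). Subjects with a
missing genotype at a combination's loci are dropped for that combination
only.

**Balanced accuracy.** Pseudo-cases are subjects with `S_i > 0` (zero →
pseudo-control). Two weightings are offered: `count` (plain confusion
matrix, used by the MDR-reduction oracle) and `score` (each subject weighted
by `|S_i|`, the default — the natural weighting when the statistic itself is
score-based; since the method defines case-ness by score sign, magnitude
carries the information). BA is invariant to positive rescaling of the
scores under both weightings. When a fold has no pseudo-case or no
pseudo-control its BA is undefined: it is flagged, excluded from means with
a warning, never silently zeroed.

**Cross-validation and selection.** Folds are a seeded uniform shuffle
(optionally stratified by score sign). Scores are computed once on all
subjects — they do not depend on genotypes — and only the cell labelling is
re-trained per fold. The fold-best combination maximizes train BA computed
on the training portion only, ties breaking to the lexicographically first
combination; CVC counts fold-best wins and always sums to the number of
folds. The final model maximizes CVC, then mean test BA, then lexicographic
order. Search is exhaustive over orders 1..k (default k_max 2, hard cap 4,
order >2 only for ≤64 loci); no stochastic search.

## Screening

Stage 1 fits one covariate-adjusted univariate GLM per locus and trait
(additive coding, homogeneous effect) and ranks by model-based Wald p-value;
the per-trait top-N lists (default N=50) are unioned. Stage 2 refits each
candidate with the heterogeneous-effect GEE across all traits and keeps
those with joint sandwich-Wald p below the threshold (default 1e-4). No
multiple-testing correction is applied — the thresholds are raw by design
and fully configurable. Non-convergent fits are ranked last with a flag. An
empty stage-2 survivor set falls back to the full candidate list with a
warning so the pipeline can continue.

## Synthetic-data generator

The simulator emulates the population-cohort setting the package targets:

- **Genotypes**: independent loci in HWE, dosage ~ Binomial(2, MAF).
  No linkage disequilibrium — deliberately out of scope.
- **Covariates**: age ~ N(51.4, 8.8²), sex ~ Bernoulli(0.5), BMI ~
  N(24.4, 3.1²), matching typical middle-aged cohort summaries; their
  probit-scale effects default to (0.25, 0.15, 0.20) on standardized
  values — modest, realistic confounding.
- **Binary occasions**: a shared latent Gaussian factor with exchangeable
  latent correlation is thresholded per subject so each marginal equals the
  penetrance-implied probability; a global probit offset is root-solved so
  the population prevalence hits the target (default 0.13, the prevalence
  of the motivating hypertension panels). The latent correlation is
  calibrated numerically (bivariate-normal orthant probabilities) to a
  target binary phi correlation, default 0.35 — the middle of the 0.32–0.48
  range reported for the motivating blood-pressure traits. Shared covariate
  effects add a little extra between-occasion correlation beyond the
  calibrated value; the calibration targets the covariate-free margins and
  the tests accept the documented band. For gaussian outcomes the error
  correlation is adjusted exactly so the *total* phenotype correlation hits
  the target.
- **Epistasis**: the default scenario plants a *pure* two-locus interaction:
  an XOR-like checkerboard table (odd dosage sums carry relative risk ~2) is
  iteratively proportionally rescaled until both HWE-weighted single-locus
  margins equal the prevalence, leaving interaction with numerically zero
  marginal effects. Default study size: n=1000 subjects and 10 loci (the
  planted pair plus 8 nulls) — a desk-scale analogue of a ~35-SNP
  post-screening candidate panel, chosen so power is neither 0 nor 1.
  The cell effect is shared across occasions (the shared-pleiotropy setting
  the multivariate method is built for).

What passing tests on these data do **not** show: robustness to LD between
loci, to ascertainment/case-control sampling, to occasion-specific
interaction effects, to non-exchangeable longitudinal dependence, or to
covariate-genotype confounding — none of which the generator produces.

## Power and stability reporting

`run_power_study` runs multivariate GMDR and per-occasion univariate GMDR
side by side on each replicate. It reports selection power (fraction of
replicates where the planted pair is the selected best model among all
k-locus models), the planted pair's CVC, and two spread measures of the
selected model's test BA: the SD across replicates, and
`mean_fold_sd_test_ba` — the across-fold SD within a replicate, averaged
over replicates. The stability comparison between multivariate and
univariate analyses uses the fold-level quantity: in a single-cohort
analysis the distribution of test BA one can actually observe is the
across-fold one, and aggregating occasions reduces exactly that
within-study score noise. The across-replicate SD of the selected model's
mean test BA is dominated by dataset and selection variability common to
both routes and does not discriminate.

## Numerical choices

- Convergence 1e-8 on the max coefficient step, 50 iterations per phase.
- Linear predictors clipped at ±30 under the logit link; means pinned
  within 1e-10 of the bounds afterwards are treated as separation.
- φ floored at 1e-12 when used as a divisor (all-zero residuals).
- Dosages are re-oriented to minor-allele counts after subject filtering;
  QC drops loci with missing fraction > 0.5% or MAF ≤ 0.01 (defaults),
  pooled or per-stratum.
- All randomness flows through `numpy.random.default_rng` seeded from the
  run seed; identical (config, seed) reproduce byte-identical outputs.

## Problem sizes used in the checks

The bundled checks run at desk scale, chosen to exercise every code path
with clear statistical margins: 1,000 random small tables for the exact MDR
reduction; 20 datasets for GLM equivalence; 200 replicates of n=2000 (and
one of n=5000) for coefficient coverage and working-correlation recovery;
100 replicates at the default study size for null CV calibration; 50
replicates × 100 null SNPs at n=2000 for screening calibration; and 60
replicates of the default epistasis scenario for power and stability.
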