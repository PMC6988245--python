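# Methods

This note records the statistical model behind each stage, the defaults and
why, the simplifications made where a published pipeline relies on
package-internal heuristics, and what the synthetic tests do and do not
establish.

## Synthetic data model

Counts for gene *g* in sample *j* are negative binomial with dispersion α
(variance μ + αμ²) and mean

μ_gj = depth_j · 2^( baseline_g + tissue_gt + diet_gdt + batch_b + λ_g f_m(j) )

- **baseline_g** ~ N(μ₀, σ₀²) in log2 units (defaults 5, 2: median ≈ 32
  counts with a heavy upper tail, a realistic desk-scale depth).
- **tissue_gt** ~ N(0, 2²) per gene × tissue: tissue differences dominate
  expression variation, as in real multi-tissue designs.
- **diet_gdt**: a fraction `pi_de` (default 0.2, matching the ~20% of genes
  the motivating design found diet-responsive) of genes get a DR and an HS
  effect relative to C. Magnitudes are |N(0, effect_size_sd)| (or a fixed
  value via `effect_size_fixed`); signs are assigned so that **exactly**
  round(rho_concord · n_de) genes have sign(LFC_DR) = sign(LFC_HS) — the
  concordance fraction is constructed, not sampled. Each tissue's effect is
  the base effect times a log-normal perturbation exp(N(0, interaction_sd)),
  which creates diet×tissue interaction without ever flipping a sign, so the
  constructed concordance fraction holds exactly in every tissue.
- **batch_b** ~ N(0, 0.2²), one scalar offset per replicate batch.
- **modules**: each planted module has a latent standard-normal factor over
  samples and a constant positive loading λ shared by its members, added on
  the log2 scale. Positive loadings give positive pairwise correlations, the
  structure a signed network detects.
- **depth_j**: log-uniform on [0.5, 2.0], matching the size-factor spread
  reported for the motivating experiment.

Default dispersion α = 0.05 is a conventional bulk RNA-seq value; the
motivating study reports no per-gene dispersions.

What the generator does **not** emulate: read-level sampling, isoform
structure, GC/length bias, gene-specific batch effects, correlated
dispersion–mean trends. A green recovery test therefore establishes that the
estimators work under the stated stochastic model, not that they are robust
to every artifact of real libraries.

## Preprocessing

- **Size factors**: median-of-ratios — s_j = median over genes with
  all-positive counts of k_gj / geometric-mean(k_g·). Errors if no gene is
  everywhere positive.
- **Filters**: count filter keeps genes with ≥10 reads in ≥2 samples;
  variance filter keeps rows with unbiased (n−1) sample variance ≥ 1. Both
  thresholds configurable; both filters idempotent. The two filters are
  exposed independently because the exact interleaving of transcript- vs
  gene-level filtering in the motivating pipeline is not recoverable.
- **Transform**: log2(k/s + 1). This is a deliberate, exactly testable
  stand-in for regularized-log transforms, whose gene-wise shrinkage is a
  package-internal procedure; it preserves the monotone, variance-damping
  intent. Output provenance is recorded in `DataFrame.attrs`.
- **Surrogate variable**: regress each gene on protected factors
  (diet, tissue) + batch, take the first right singular vector of the
  residual matrix, standardized to zero mean and unit norm, with a
  deterministic sign convention. Exactly one SV is returned (the design role
  the motivating analysis found); iterative reweighting is intentionally
  omitted for determinism.
- **Batch removal**: per gene, least squares on [protected | batch | SV];
  only the fitted batch and SV components are subtracted. Confounding of
  batch with a protected factor raises an error.

**Known interaction**: on data whose dominant residual structure is a real
co-expression module (as in the planted-module test world), residual-PCA SVA
captures that module's factor and batch removal then deletes biological
signal. The module-detection tests therefore use batch-only correction; on
real data the single SV is assumed to track unmodelled technical structure.

## Differential expression

- **Dispersion**: per-gene method of moments on size-factor-normalized
  counts, pooling within-cell variance across diet×tissue cells:
  α_g = max(1e-8, (s² − μ̄)/μ̄²). The floor prevents degenerate likelihoods
  for under-dispersed genes. No trended/shared shrinkage: the motivating
  pipeline's "local" fit is package-internal, and the simple estimator is
  exactly testable (it is consistent; at n = 18 it is noisy, which the
  calibration tests absorb).
- **GLM**: NB log-likelihood with log link and log(s_j) offsets, fitted by
  IRLS (statsmodels). Convergence tolerance 1e-8, cap 100 iterations;
  non-converged fits propagate p = NaN and are excluded from adjustment with
  a logged count.
- **LRT**: 2Δll clipped at zero against the χ² upper tail with df = the
  difference in parameter count. Factor coding is treatment-contrast with
  reference levels C (diet) and B (tissue); the LRT is invariant to the
  choice of reference.
- **Fold changes**: log2((μ̂_A + c)/(μ̂_B + c)) on mean normalized counts,
  pseudocount c = 0.5. This moderation is a deterministic, closed-form
  stand-in for prior-based shrinkage: it damps low-count fold changes and
  preserves ranking, and it is exactly antisymmetric under group exchange.
  Fold changes are per-pair group-mean contrasts rather than model-4
  coefficients; the motivating text does not determine which was used.

## Concordance test

Observed statistics: Pearson r between LFC(D₁ vs ref) and LFC(D₂ vs ref),
and the proportion of genes with the same nonzero sign in both (exact zeros
count in the denominator only — measure-zero for continuous data). The null
rebuilds pseudo-diets by drawing, per true diet, `per_pseudo` samples (2 by
default) for each pseudo-diet without replacement within a draw; the
partition space per tissue has (6!/2!2!2!)³ = 729,000 labeled outcomes, and
the 100 draws are sampled uniformly with replacement from it. Null fold
changes use the same moderated-LFC procedure as the observed statistics
(statistic/null symmetry, not a per-permutation GLM refit). The test is
one-sided ("greater"): the scientific hypothesis is excess concordance.
Under a null simulation the null proportion centers near 2/3 — the
arcsine law value 1/2 + arcsin(1/2)/π for two noise ratios sharing a
reference — and the null correlation near 1/2, which is the
shared-reference artifact the test is built to absorb.

## Co-expression modules

- **Network**: signed adjacency ((1+cor)/2)^β; Pearson correlation
  throughout; constant genes get zero correlation with a log entry.
- **Soft threshold**: the scale-free fit index regresses log10 frequency on
  log10 mean connectivity over 10 equal-width connectivity bins and returns
  r²·sign(−slope); the selector picks the smallest candidate power reaching
  0.90, else the argmax with a warning. Equal-width binning is used because
  equal-occupancy bins make the frequency response constant by construction
  (degenerate regression).
- **Clustering**: average linkage on 1 − TOM with a **static** height cut
  (default 0.95) and minimum module size 30. The static cut replaces the
  dynamic hybrid tree cut deliberately: identical height/min-size
  parameters, exact reproducibility, hand-checkable dendrograms. The cost is
  sensitivity to the absolute TOM scale, hence:
- **Power for the planted-module tests**: with a static cut, a clean module
  of uniform within-adjacency *a* has within-TOM ≈ *a*, so detection
  requires ((1+ρ)/2)^β > 1 − cutHeight. At the planted within-correlation
  ρ ≈ 0.7 this bounds β < 18.4; tests use β = 10, which maps ρ = 0.7 to
  a ≈ 0.2 (dissimilarity ≈ 0.8, safely below the 0.95 cut) and background
  correlation 0 to a ≈ 10⁻³. The real-data default β = 23 remains the
  config default; it presupposes the much larger correlations of
  genome-scale hub genes. The scale-free selector is not used on planted
  blocks: block covariance is not scale-free, and the fit index increases
  monotonically as the network sparsifies, selecting arbitrarily large
  powers.
- **Eigengenes**: first right singular vector of the gene-standardized
  module submatrix, unit norm, oriented to correlate non-negatively with the
  module's mean standardized profile (deterministic up to exact ties, which
  fall back to a first-nonzero-positive rule).
- **Merging**: greedily merge the pair with the highest eigengene
  correlation while it exceeds the threshold (strict >, default 0.9; the
  motivating text is inconsistent between ≥ and >, and the boundary is
  configurable), recomputing eigengenes after each merge; the merged module
  keeps the lexicographically smaller label; unassigned never merges.
- **Robustness**: 100 resampled networks keeping 4 of 6 replicates per
  diet×tissue cell, rebuilt with identical parameters including merging. A
  resampled module matches a full-data module when it contains ≥10% of that
  module's genes; best absolute overlap wins, ties to the lexicographically
  smallest label. Gene support = fraction of resamples in which the gene
  lands in a module matched to its own; genes under 50% support are
  unassigned. The resampled networks reuse the full-data power.
- **Eigengene ANOVA**: two-way ANOVA with interaction via sequential sums of
  squares, valid because the balanced diet×tissue design is enforced
  (unbalanced input raises an error rather than silently switching SS
  types); BH across modules within each term.

## Gene sets

The set-level t statistic is a single Welch two-sample t of per-gene log2
fold changes, set versus the rest of the background ("mean change" is the
difference in means). This collapses the per-sample-pair meta-test of
GAGE-style pipelines into one contrast-level test — the reported quantities
(mean change, FDR) keep their meaning, and the collapse is deterministic.
Two-sided by default; minimum set size 10 after background intersection
(conventional; configurable). Fisher over-representation uses the one-sided
hypergeometric tail with Bonferroni correction, the standard pairing for GO
term scans. The per-gene statistic fed to the t-test is the fold change;
the column is configurable at the call site.

## Numerical choices

- Empirical p-values use the add-one rule and can never be zero; the
  smallest attainable value at M = 100 is 1/101.
- BH adjustment passes NaN p-values through untouched and excludes them
  from m.
- TOM is symmetrized and clipped to [0,1] after the vectorized computation
  to absorb floating-point asymmetry at the 1e-16 level.
- All stage seeds derive from one global seed via a CRC32 hash of the stage
  name, below 2³¹, so stages are independently reproducible.

## Test-world calibrations (stated a priori)

- Planted-module world: loading λ = 0.53 with baseline log2-mean 7 and
  α = 0.05 gives within-module expression correlation ≈ 0.7 by the variance
  decomposition λ²/(λ² + noise), noise ≈ (1/μ + α)/ln²2; tissue effects are
  zeroed so correlation structure comes only from the factors.
- LFC-recovery world: effects with sd 1 are planted on **every** gene
  (pi_de = 1). Scoring a 20%-planted world dilutes the correlation to ≈0.85
  analytically (80% of pairs are noise-vs-zero), which measures the mixture
  proportion rather than estimator accuracy.
- Concordance calibration and power use the 3000-gene × 18-sample scale at
  which the artifact statistic is defined elsewhere in the suite.

## Known limitations

- The dispersion estimator is unshrunken; at 6 replicates per cell its
  sampling error is substantial, and the LRT inherits mild miscalibration
  that the FDR-level tests bound but do not remove.
- The static height cut cannot split nested or touching modules the way a
  dynamic tree cut can; module counts on real data will differ.
- One surrogate variable only; hidden structure with rank > 1 is not
  captured, and SVA can absorb genuine co-expression (see above).
- Fold-change moderation by pseudocount is coarser than prior-based
  shrinkage for genes with very low counts.
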