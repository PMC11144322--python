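# Methods

`gwtwas` implements a two-stage transcriptome-wide association study (TWAS)
that uses both cis- and trans-eQTL, with a Cauchy omnibus combination across
tissues, and a synthetic-data generator that makes every stage testable
against known ground truth.

## Model

**Stage I — sparse eQTL weights.** For a gene with (covariate-adjusted,
standardized) expression trait ε_g over n reference samples,

    ε_g = X_cis w_cis + X_trans w_trans + ε,   ε_i ~ N(0, σ_ε²),

where X holds standardized dosages of genome-wide variants, split into cis
(within ±1 Mb of the TSS, inclusive, one convention everywhere) and trans
(everything else). Sparsity comes from spike-and-slab priors per group:

    w_cis,i   ~ π_cis  N(0, σ²_cis σ_ε²)  + (1 − π_cis)  δ₀,
    w_trans,i ~ π_trans N(0, σ²_trans σ_ε²) + (1 − π_trans) δ₀.

The fitted quantity per variant is the posterior causal probability (PCP,
the posterior inclusion frequency) and the posterior mean effect conditional
on inclusion; their product w̃ = PCP × effect is the eQTL weight.

**Stage II — burden association.** Given GWAS single-variant Z-scores Z_l
and a reference LD covariance V = Cov(X_ref) with σ̂_l = sqrt(V_ll),

    Z_g = Σ_l w̃_l σ̂_l Z_l / sqrt(w̃ᵀ V w̃),   p = 2·Φ(−|Z_g|).

**Omnibus.** Per gene, the K per-tissue p-values are combined by
T = (1/K) Σ tan{(0.5 − p_i) π}; under the null T is approximately standard
Cauchy, so p_combined = 0.5 − arctan(T)/π. The approximation is robust to
between-tissue correlation and most accurate for small p-values.

## Fitting: blocked EM-MCMC

Genome-wide fitting per gene is made tractable by blocking and screening:

1. **Segmentation.** Variants are cut into fixed-size contiguous blocks per
   chromosome (default 1,000 variants at real scale, 50–100 in tests). The
   fixed-size partition stands in for LD-based "approximately independent"
   blocks; block boundaries are configuration, so an externally computed
   partition can be supplied.
2. **Screening.** Every block overlapping the cis window is kept; any other
   block is kept iff its best single-variant p-value is strictly below 1e-5.
3. **E-step.** Within each selected block, a Gibbs sampler scans variants:
   for variant j with prior odds from its group's π, the spike/slab
   posterior odds use the conjugate normal marginal likelihood; on
   inclusion the effect is drawn from its exact conditional N(m_j, v_j).
   This is the Metropolis-within-Gibbs scheme with the full conditional as
   proposal (acceptance 1). The implementation maintains c = Gw (G = XᵀX)
   incrementally, making each variant update O(1) when the state does not
   change; the kernel is numba-compiled. Blocks are sampled independently
   of one another, each with an RNG seeded from (global seed, EM round,
   block offset), so results do not depend on block processing order or on
   worker count.
4. **M-step.** Pooled posterior summaries update the hyperparameters:
   π_group ← (Σ PCP + a)/(n_group + a + b) with Beta pseudocounts
   (a = 0.1, b = 10 by default — weakly informative toward sparsity),
   σ²_group ← Σ PCP·E[w²|incl] / (σ_ε² Σ PCP) floored at 1e-6, and
   σ_ε² ← RSS/n evaluated at the posterior-mean weights. EM stops at the
   relative-change tolerance (1e-3) or the round limit.

Defaults are 10,000 MCMC sweeps + 2,000 burn-in per EM round and 3 rounds;
π_cis = 1e-3, π_trans = 1e-5, σ² = 1 at initialization. Tests and the
acceptance benchmarks run 1,200–2,500 sweeps and 2 rounds: with the strong
planted signals and ≤400 screened variants of the simulated studies the
chain mixes within a few hundred sweeps (the per-sweep flip diagnostic and
the stability of PCPs across seeds bear this out), so the shorter chains
keep Monte-Carlo error well below the tested margins.

Diagnostics recorded per fit: the fraction of sweeps in which the inclusion
state changed (reported as the acceptance rate, warned outside
[0.01, 0.99]), the total per-update flip rate, and the mean/SD of the
post-burn-in log-likelihood trace.

## GWAS Z-score convention

Single-variant statistics (simulated and consumed) are the asymptotic Wald
form with the trait variance as the residual-variance estimate,
Z_l = sqrt(n−1)·cor(y, x_l). At GWAS sample sizes this is indistinguishable
from the exact OLS t-statistic (relative difference ~Z²/n), and it makes the
burden statistic algebraically identical to the individual-level regression
of the trait on the raw-dosage GReX Σ_l w̃_l x_l whenever the LD reference
equals the GWAS cohort — the oracle-equivalence property the test suite
checks to 1e-6. With an exact-t convention that identity holds only to
O(Z²/n) and the equivalence test would measure the convention, not the
implementation.

## Preprocessing

* **Variant QC** (all strict inequalities): missing rate < 0.20, MAF > 0.01,
  HWE chi-square (1 df, expected counts from the sample allele frequency)
  p > 1e-5. Monomorphic variants return HWE p = 1 (no departure testable)
  and are instead removed by the MAF filter. Missing dosages that survive
  are mean-imputed per variant; HWE counting ignores non-integral
  (imputed) entries, which keeps filtering idempotent.
* **Normalization.** Median-of-ratios size factors (reference genes are
  those with no zero count), natural-log transform with offset 1, retention
  of genes with value > 1 in strictly more than 10% of samples, then
  per-gene centering and scaling (SD 1, ddof 1). Genes constant across
  samples are unscalable and dropped (tolerance 1e-12 absorbs log
  rounding).
* **Outlier samples.** Average-linkage hierarchical clustering on cosine
  distance between sample profiles; the dendrogram is cut at a configured
  cluster count (default 10 — the rule needs clusters small enough to
  isolate an aberrant batch, and the result is insensitive to the exact
  count in the planted-outlier tests). Each sample's squared Mahalanobis
  distance is computed on the top principal components (default dimension
  10) with each axis centered by its median and scaled by its normalized
  MAD; the robust center/scale prevents a compact aberrant block from
  inflating its own covariance and masking itself, and the subspace keeps
  the estimate well-conditioned when genes ≫ samples. Chi-square p-values
  (df = subspace dimension) are Bonferroni-corrected over samples; clusters
  with ≥ 60% flagged samples are excluded wholesale. A classical
  full-covariance mode exists for n ≫ genes.
* **Covariate adjustment.** Per-gene least-squares residuals on an
  intercept, top genotype principal components, top principal components of
  the normalized expression matrix (a deterministic surrogate for
  probabilistic hidden-factor models — factor counts are configuration;
  large cohorts typically use tens of factors, the bundled mini study uses
  0–2 because it has ~15 genes), and supplied covariates (categoricals
  one-hot with the first level dropped). Residuals are re-standardized.
  Rank-deficient designs raise an error naming the collinear columns.

## Synthetic data

The generator emulates the structure the method assumes, with known truth:

* **Genotypes.** Per block, two haplotype chains of latent AR(1) Gaussians
  are thresholded at the Hardy–Weinberg quantile of each variant's MAF
  (drawn uniformly from the configured range) and summed to dosages. The
  latent correlation of each adjacent pair is calibrated numerically
  (Owen's-T bivariate normal CDF + root finding) so the *dosage*-scale
  adjacent correlation equals `block_ld_rho`; thresholding otherwise
  attenuates it. For very unequal MAFs the target can exceed the Fréchet
  bound for binary margins, in which case the latent correlation caps at
  0.999 and the realized correlation falls at the attainable maximum.
  Blocks are independent; correlation decays geometrically within a block.
* **Expression.** The genetic component (on standardized dosages) is
  rescaled so its sample variance is exactly h², and noise has variance
  1 − h² (overridable, 0 gives a noiseless trait). True weights are shared
  across tissues; noise is drawn independently per tissue.
* **GWAS.** The trait is α·Σ_genes GReX_g plus a polygenic background
  scaled to its variance fraction plus Gaussian noise (background + noise
  variance 1); the cohort is simulated at the individual level and then
  summarized, which is what enables the individual-level oracle tests.
  The mediated-trait architecture is a configurable stand-in; nothing about
  a real disease cohort is implied by its defaults (α = 0.3, background
  h² = 0.1).
* **Fixtures on disk.** Counts are reconstructed from traits by inverting
  the normalization (counts = round(sf·(exp(t + 5) − 1)) with per-sample
  log-normal size factors); the +5 log offset keeps counts large enough
  that integer rounding perturbs the recovered trait by ≲0.04 at the
  smallest counts. Optional h² = 0 filler genes stabilize median-of-ratios
  estimation in small fixtures.

What the generator does **not** emulate: recombination-map LD, population
structure and relatedness, imputation dosage uncertainty, count
overdispersion beyond the log-normal depth model, and context-specific
(cell-type) eQTL. Passing tests therefore demonstrate correctness of the
algorithms under the assumed model, not robustness to those real-data
complications.

## Declared conventions where the method description is open

* **Trans-driven classification:** fraction of the burden numerator's
  magnitude contributed by trans variants, Σ_trans |w̃|σ̂ / Σ_all |w̃|σ̂,
  with genes at ≥ 0.5 labeled trans-driven (inclusive). A variance-based
  alternative (share of the weighted LD quadratic form, cross terms
  ignored) is available behind `trans_method="variance"`.
* **Bonferroni denominators** count only testable genes (a computed p);
  genes with no surviving weights or no GWAS overlap are reported
  untestable, never p = 1. Significance is strict (p < α/m).
* **Omnibus with missing tissues:** K adapts to the tissues where the gene
  was testable; genes testable nowhere are absent from the omnibus table.
* **Harmonization:** match on variant id; swapped ref/alt flips the GWAS Z
  sign; strand-ambiguous (A/T, C/G) variants and allele mismatches are
  dropped and counted.
* **PCP floor:** variants with PCP < 0.01 are dropped from weight sets
  (strict), keeping weight files sparse without touching the statistic's
  scale invariance.

## Numerical notes

* Cauchy combination: inputs at 1 are clipped to 1 − 1e-16; for p < 1e-15
  the tangent is replaced by its asymptotic equivalent 1/(pπ), keeping the
  transform monotone and stable down to p ~ 1e-300.
* Burden test: genes with all-zero weights or zero weighted LD variance
  raise an untestable-gene error rather than returning a p-value.
* Gibbs updates clip the inclusion log-odds at ±35 before the logistic.
* All TSV outputs use fixed float formats, and every random draw descends
  from the global seed plus stable labels (cohort, tissue, gene id hash,
  EM round, block offset), giving byte-identical reruns at any worker
  count.

## Problem sizes

Simulated studies in the tests and benchmarks use 500–2,000 reference
samples, 1,000–5,000 GWAS samples and 100–1,000 variants in blocks of
50–100 — large enough that Monte-Carlo noise sits well inside the asserted
margins (e.g. binomial SD ≈ 0.007 for a 0.05 type-I rate over 1,000 genes),
while a full suite run plus the benchmark script completes in a few minutes
on one CPU. The bundled mini study (600 variants, 3 architected + 12 filler
genes, 2 tissues) exercises every stage end to end.

## Known limitations

* Blocks are sampled independently in the E-step; signal in one block acts
  as extra noise for another. With screening this mainly inflates σ_ε²
  slightly and is the price of block-parallel sampling.
* PCPs are posterior inclusion frequencies under the fitted
  hyperparameters; they are not calibrated posterior probabilities under
  hyperparameter uncertainty.
* The Mahalanobis subspace dimension and dendrogram cut are heuristics;
  pathological designs (e.g. many small real clusters) may need the
  configuration adjusted.
* The trans-fraction metric is a declared convention (see above); other
  definitions can reorder genes near the 50% boundary.
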