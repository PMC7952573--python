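# Methods

## The model

`gblupkit` implements GWAS-informed genomic prediction for quantitative
traits with the classical genomic BLUP machinery. The working model is
the linear mixed model

    y = X β + W u + ε,        u ~ N(0, I σu²),   ε ~ N(0, I σε²),

where `y` holds phenotypes for n individuals, `X` the fixed covariates
(intercept, age, sex, BMI, and optionally principal components of the
genomic relationship matrix), and `W` the column-standardized genotype
matrix with entries

    w_ij = (z_ij − 2 p_j) / sqrt(2 p_j (1 − p_j)),

`z_ij ∈ {0,1,2}` counting copies of allele 1 of SNP j and `p_j` its
allele-1 frequency. Collapsing the SNP effects into total genetic
values `g = W u` gives the equivalent form

    y = X β + g + ε,          var(y) = A σg² + I σε²,

with `A = W W′ / K` the genomic relationship matrix over K SNPs. The
pipeline estimates (σg², σε²) by AI-REML, computes BLUPs of `g`,
back-solves per-SNP effects, scores held-out individuals, and compares
SNP-subset selection strategies by repeated cross-validation.

## GRM estimator

Off-diagonals are the standardized cross-products `(W W′/K)_{ii′}`.
Diagonals use the homozygosity-based estimator

    A_ii = 1 + (1/K) Σ_j [z_ij² − (1 + 2p_j) z_ij + 2p_j²] / (2 p_j (1 − p_j)),

whose per-SNP expectation is exactly 1 under Hardy–Weinberg genotype
frequencies. The `(1 + 2p)` sign matters: with `(1 − 2p)` the per-SNP
expectation is `1 + 4p²/(1−p)` and the mean diagonal drifts far above 1;
a regression test locks the implemented sign. Missing genotypes
standardize to `w = 0` (mean imputation at `2 p_j`); the pipeline does
not impute genotypes otherwise.

For the algebraic identities used in testing (ridge duality, the
projection `W û = ĝ`) the plain cross-product matrix `A = W W′/K`
(`cross_product_grm`) is the exact object; the homozygosity diagonal
perturbs them at the O(1/K) level. With own-frequency standardization
the columns of `W` are centered, so `W W′` always has the all-ones
vector in its null space; back-solving therefore uses the
eigendecomposition pseudo-inverse (eigenvalues below 1e−10 of the
largest are dropped), which returns the minimum-norm pre-image.

## AI-REML

`reml_ai` maximizes the restricted likelihood of
`var(y) = A σg² + I σε²`. One eigendecomposition `A = U D U′` is taken
up front; rotating `y` and `X` by `U` makes `V` diagonal, so each
iteration is O(n p²). The first update is an EM-REML step (which cannot
decrease the restricted likelihood), then average-information Newton
steps `θ ← θ + AI⁻¹ s` with step-halving back toward the current point
whenever a step would lower the likelihood. Components are constrained
to ≥ 1e−6 · var(y) by truncation. Convergence requires
`|Δ log L_R| < 1e−4` and component changes `< 1e−6 · var(y)`
(max 100 iterations; typical fits converge in 4–8). `SE(ĥ²)` comes from
the inverse AI matrix by the delta method. The reported restricted
log-likelihood is

    −½ [ log|V| + log|X′V⁻¹X| − log|X′X| + y′Py ];

the `−log|X′X|` term makes it invariant to reparameterization of the
fixed-effect basis, which is asserted by test. `profile_loglik` provides
an independent check: on a grid of heritability ratios it maximizes the
likelihood over the total variance in closed form,
`σ̂² = y′P₀y/(n−p)` with `V₀ = h² A + (1−h²) I`; the AI-REML optimum
must dominate the grid and sit within one grid step of its maximizer.

Identity-proportional GRMs make the two components unidentifiable;
`reml_ai` raises in that case rather than returning an arbitrary split
(the profile over h² is exactly flat, which `profile_loglik` shows).

### Sampling precision of ĥ²

With K unlinked SNPs the off-diagonal variance of A is 1/K, giving the
standard GREML approximation `SD(ĥ²) ≈ sqrt(2K)/n`. At the simulation
scale used here (n = 1000, K = 2000) that is ≈ 0.063. Consequences
worth keeping in mind when reading test output: null (h² = 0) estimates
sit at the zero boundary in about half of replicates and follow a
half-normal with SD ≈ 0.06 otherwise, so single null replicates above
0.05 are expected behaviour, not estimator bias — the recovery
experiments (mean ĥ² over replicates at h² = 0.5) are the calibrated
check of location.

## Prediction

Fixed effects are GLS, `β̂ = (X′V⁻¹X)⁻¹X′V⁻¹y`, and the genetic-value
BLUP is `ĝ = σ̂g² A V⁻¹ (y − Xβ̂)` (verified against Henderson's
mixed-model equations). SNP effects on the standardized scale are
`û = W′A⁻¹ĝ / K` — the SNP count K is the only denominator that makes
`û = W′(WW′)⁻¹ĝ`, i.e. the minimum-norm pre-image — and on the
allele-count scale `û*_j = û_j / sqrt(2 p_j (1 − p_j))`. `û` equals the
SNP-BLUP ridge solution `(W′W + λI)⁻¹W′(y − Xβ̂)` with
`λ = K σ̂ε²/σ̂g²` (tested to 1e−6, including rank-deficient A).

Held-out individuals are scored either as `w_test · û` with test
genotypes standardized using **training** frequencies, or as
`z_test · û*` on raw dosages (PLINK-style scoring, as a sum over SNPs
rather than an average — a dialect choice; the two dialects differ by a
factor that leaves correlations unchanged). The two modes differ per
individual by a constant, so all correlation-based accuracy measures
are identical (tested to 1e−10). Test panels are aligned to training
effects by SNP id; allele flips (allele1/allele2 swapped) are detected
and the dosage reversed, anything else is an error. Missing test
genotypes are mean-imputed.

## QC cascade

In order: (1) drop SNPs then samples with missing rate > 0.2;
(2) the same at 0.02; (3) a no-op sex-check stage logged for report
parity (no X chromosome in the data model); (4) drop SNPs with
MAF < 0.05; (5) drop SNPs with exact-test HWE p < 1e−6; (6) drop
samples whose heterozygosity rate (n_het / n_non-missing) lies outside
mean ± 3 SD. Every step recomputes statistics on the current matrix,
and within each missingness stage SNP removal precedes sample removal.
The strict-stage threshold is read as missing rate > 0.02 (call rate
< 0.98); a literal call-rate-below-0.02 cutoff would be vacuous after
the 0.2 stage. The HWE test is the exact conditional test (enumeration
of heterozygote counts given allele counts, no mid-p); a χ² fallback is
provided. All thresholds are configurable in `QCConfig`.

One caveat established during testing: ±3 SD trimming is *not*
idempotent in principle — the threshold is recomputed from the trimmed
sample, so a re-run re-trims roughly the Gaussian tail mass
P(|z| > 3) ≈ 0.27% of samples. The SNP filters are exactly idempotent.
The cascade is designed as a single pass, matching usual practice.

## GWAS and covariates

The association scan is per-SNP OLS of the trait on
[1, covariates, PCs, z_j] with a two-sided t test on the dosage
coefficient; samples missing z_j are dropped per SNP (casewise
deletion). Complete SNPs share one QR residualization, so a scan over
thousands of SNPs is a single matrix product. Monomorphic SNPs are
flagged with p = 1. PCs are the top eigenvectors of the GRM (sign fixed
by making the largest-magnitude loading positive); 20 by default per
the motivating design, configurable down for small unstructured
simulations where they only add fixed-effect noise. Family-aware mixed
models are deliberately not used for the scan itself (out of scope);
on the unrelated synthetic samples OLS + PCs is the appropriate model.

Phenotype preparation utilities implement the lipid-panel conventions:
Friedewald LDL-C = TC − HDL-C − TG/5 (mg/dL; a warning flags
TG > 400 mg/dL where the approximation breaks down), natural-log
transformation for the right-skewed TG, and bidirectional stepwise
covariate selection by AIC starting from the full {age, sex, BMI}
model. AIC admits a null covariate with probability
P(χ²₁ > 2) ≈ 0.157 — that is the criterion's intrinsic behaviour, and
the tests assert it rather than a zero false-inclusion rate.

## Cross-validated subset comparison

`run_cv_strategies` implements the repeated k-fold engine (10 folds ×
10 repeats by default; per repeat a seeded permutation is split into
near-equal folds). Per cell, **everything is learned on the discovery
split only**: GWAS ranking, allele frequencies, PCs, variance
components, SNP effects, and the covariate-adjustment coefficients used
to residualize the validation phenotypes. A `pooled_adjustment` flag relaxes
the last point (adjustment fitted on the full sample) for sensitivity
comparison; on unstructured simulations the difference is small. The
accuracy index per cell is the Pearson correlation between predicted
genetic values and adjusted phenotypes of the validation fold; the
average over all cells is the strategy's score. Cells whose REML fails
to converge are excluded from the mean with a reported count (they do
not occur in the shipped simulations).

Strategies: `top_pct` takes the `ceil(f·K)` SNPs with smallest
discovery-GWAS p-values (ties broken by genomic position for
determinism); `random_matched` a seeded uniform draw of the same size
(per-cell seeds derived from the CV seed); `gene_list` all SNPs inside
user intervals ± a 10 kb flank (1-based closed intervals); `"all"` the
full panel. Several strategies evaluated together share the per-cell
GWAS, GRM and eigendecomposition, so the comparison costs little more
than a single strategy.

"Shared SNPs" are the intersection of selected sets over all cells;
`shared_heritability` rebuilds a GRM from the shared set over **all**
individuals and re-estimates h² with the covariates as fixed effects —
the gene-based heritability of the consistently selected SNPs.

Under the null (h² = 0), all cells of one dataset share a single
residual draw, so the 100-cell mean correlation keeps an irreducible
per-dataset Monte-Carlo component with SD ≈ 0.05 at n = 500 even
though its expectation is zero (confirmed over 40 independent
datasets). Null-calibration checks therefore average over several
independent datasets.

## Synthetic data

`simulate_genotypes` draws per-SNP allele frequencies uniformly on the
configured MAF range (default 0.05–0.5, the post-QC range of the
motivating design) and builds genotypes as sums of two independent
haplotypes, each thresholding a latent standard Gaussian at Φ⁻¹(p_j) —
so per-SNP marginals are exactly Binomial(2, p_j) and HWE holds by
construction. LD, when requested, is a Gaussian-copula block model:
within a block the haplotype latents share an exchangeable correlation
`ld_rho`. Block size 1 (the default) gives independent SNPs.

`simulate_phenotype` draws age ~ U(20, 70) years, sex ~ Bernoulli(0.5),
BMI ~ N(27, 4²) kg/m², with default effects 0.01/year, 0.5, and
0.03/unit on a trait whose genetic-plus-residual variance is normalized
to 1 — covariate effects of the same order as the genetic signal, as in
the lipid traits that motivate the design. Causal effects are drawn
i.i.d. normal on the standardized scale at `n_causal` SNPs and rescaled
so the realized `var(Wu)` equals `h2_target` exactly (σε² = 1 − h²);
`SimTruth` records the realized heritability, causal set, per-SNP
effects and genetic values for recovery tests. SNPs monomorphic in the
drawn sample stay causal with zero effect (they carry no variance).
All randomness flows from the single `SimConfig.seed`.

`plant_qc_violations` injects, at recorded disjoint indices: SNPs with
30% missing calls, SNPs redrawn at MAF ≈ 0.01, SNPs with zero
heterozygotes at p = 0.5 (χ² = n, far past any sane HWE threshold), and
individuals heterozygous at every SNP. The planted design guarantees
each violation is caught by exactly one cascade step, so the QC report
can be compared to planted truth *exactly*.

Family structure is not simulated by default (the motivating cohort is
family-based, but relatedness is not needed for the core correctness
checks); `mate_random_pairs` optionally creates offspring by Mendelian
sampling from random parent pairs, and a test confirms parent–offspring
GRM entries near 0.5, so relatedness effects can be probed on demand.
What the generator does **not** emulate: realistic human LD maps,
admixture, genotyping-error processes, or trait scales in physical
units. Passing tests therefore
demonstrate the statistical machinery is correct under the model's own
assumptions, not that real-cohort accuracies are reproduced — the
qualitative patterns (selected ≫ random at small fractions; top-50% ≈
all SNPs; shared-SNP heritability above the whole-panel estimate) are
the transferable claims.

## Numerical and design choices

- Problem sizes in the shipped experiments (n ≤ 1000, K ≤ 5000,
  sparse architectures with tens of causal SNPs) are desk-scale
  choices that keep every eigendecomposition dense and the full suite
  re-runnable in minutes while leaving the tested contrasts far above
  their Monte-Carlo noise floors.
- Fold sizes differ by at most 1; partitions are seeded and
  reproducible bit-for-bit.
- Equal GWAS p-values are ordered by (chromosome, position).
- The GCTA GRM binary triplet is float32 on disk (lossy); in-memory
  matrices stay float64.
- PLINK bed codec: magic `6c 1b 01`, SNP-major, 2-bit codes packed
  low-bits-first, pad bits zero; dosage mapping 00→2, 01→missing,
  10→1, 11→0 (copies of allele 1).
- One global seed derives all stage seeds via `numpy` SeedSequence;
  derived seeds stay below 2³¹.

## Known limitations

- No mixed-model (leave-one-chromosome-out) GWAS; no LD-aware effect
  shrinkage; no dominance or epistatic terms.
- Single-GRM REML only (no partitioned heritability, no bivariate
  models).
- Chromosome X and sex-discrepancy checking are out of the data model.
- Genotype imputation is replaced by mean imputation at standardization.
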