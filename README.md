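# gblupkit

GWAS-informed genomic prediction for quantitative traits: quality
control, per-SNP association, p-value-ranked SNP-subset selection,
genomic relationship matrices, AI-REML variance components, gBLUP
polygenic prediction, repeated cross-validated accuracy, and gene-based
heritability of the SNPs shared across cross-validation folds.

The package is aimed at quantitative/statistical geneticists who want a
self-contained, testable implementation of the "select SNPs by GWAS
rank, then run gBLUP on the subset" strategy — for methods work,
teaching, or benchmarking against simulated architectures — without a
cohort-scale toolchain. A synthetic-data module generates genotypes and
phenotypes with the statistical structure the method assumes (HWE
genotypes, optional LD blocks, configurable heritability and causal-SNP
fraction, planted QC violations), so the entire pipeline runs and is
validated at desk scale.

## The model

Phenotypes follow the standard additive mixed model

    y = Xβ + Wu + ε,   u ~ N(0, I σu²),   ε ~ N(0, I σε²),

with `W` the column-standardized genotype matrix,
`w_ij = (z_ij − 2p_j)/√(2p_j(1−p_j))`. Writing `g = Wu`,

    var(y) = A σg² + I σε²,   A = WW′/K,

where `A` is the genomic relationship matrix over K SNPs (off-diagonals
from the cross-products, diagonals from the homozygosity-based
estimator). AI-REML estimates (σg², σε²) and hence the SNP heritability
h² = σg²/(σg²+σε²); BLUP gives genetic values
`ĝ = σ̂g² A V⁻¹(y − Xβ̂)`, per-SNP effects are back-solved as
`û = W′A⁻¹ĝ/K` (allele-count scale: `û*_j = û_j/√(2p_j(1−p_j))`), and
held-out individuals are scored as `ĝ_test = w_test·û`. Prediction
accuracy is the Pearson correlation between scores and
covariate-adjusted phenotypes in repeated 10-fold cross-validation,
with all quantities (GWAS ranking, frequencies, PCs, variance
components, adjustment) learned on the discovery folds only.

See `docs/methods.md` for the full account of estimators, iteration
schemes, tolerances and design choices.

## Worked example

```python
import numpy as np
import gblupkit as gk

# a sparse architecture: 1000 individuals, 5000 SNPs, 50 causal, h2 = 0.5
cfg = gk.SimConfig(n_samples=1000, n_snps=5000, seed=1,
                   h2_target=0.5, n_causal=50)
g = gk.simulate_genotypes(cfg)
pheno, truth = gk.simulate_phenotype(g, cfg)

# whole-panel heritability
a = gk.compute_grm(gk.standardize(g))
x = np.column_stack([np.ones(1000), pheno[["age", "sex", "bmi"]].to_numpy()])
vc = gk.reml_ai(pheno["trait"].to_numpy(), x, a)
print(f"h2 = {vc.h2:.3f} (SE {vc.se_h2:.3f})")

# compare subset strategies under 2x5 cross-validation
res = gk.run_cv_strategies(
    g, pheno, gk.CVConfig(n_folds=5, n_repeats=2, seed=2, n_pcs=0),
    {"top1": gk.SubsetSpec("top_pct", fraction=0.01),
     "rand1": gk.SubsetSpec("random_matched", fraction=0.01),
     "all": "all"},
)
for name, r in res.items():
    print(f"{name:>5}: mean CV-r = {r.mean_r:.3f}")
```

Output (printed by the code above):

```
h2 = 0.612 (SE 0.099)
 top1: mean CV-r = 0.526
rand1: mean CV-r = 0.013
  all: mean CV-r = 0.216
```

The whole-panel REML estimate tracks the simulated heritability (0.612
vs the 0.5 target, within about one SE — single-replicate GREML
estimates at n = 1000, K = 5000 carry an SE near 0.1; averages over
replicates land on the target, as the acceptance script shows). The 50
SNPs ranked top-1% by the discovery-fold GWAS predict held-out
phenotypes far better (r = 0.53) than a size-matched random subset
(r = 0.01) and better than the full panel (r = 0.22) on this sparse
architecture — with 50 causal SNPs, the ranking concentrates the
signal while the full-panel GRM dilutes it across 5000 columns.

The same stages are available from the shell:

```bash
gblupkit simulate --n-samples 500 --n-snps 2000 --h2 0.5 --seed 1 --out-prefix sim
gblupkit qc --bfile sim --out-prefix qced
gblupkit gwas --bfile qced --pheno sim.pheno.tsv --n-pcs 20 --out assoc.tsv
gblupkit cv --bfile qced --pheno sim.pheno.tsv --subset top:0.05 --out-prefix cv_top5
```

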