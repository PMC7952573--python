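"""Synthetic genotypes and phenotypes with the structure gBLUP assumes.

Genotypes are biallelic SNPs in Hardy-Weinberg proportions: each of the
two haplotypes per individual carries allele1 where a latent standard
Gaussian falls below Phi^{-1}(p_j). Linkage disequilibrium, when
requested, comes from a Gaussian-copula block model — within a block of
``ld_block_size`` SNPs the haplotype latents share an exchangeable
correlation ``ld_rho`` (block size 1 = independent SNPs). This keeps
per-SNP marginals exactly Binomial(2, p_j) whatever the LD setting.

Phenotypes follow the standard additive model y = X beta + W u + eps
with u drawn on the standardized-genotype scale at ``n_causal`` SNPs and
rescaled so the realized genetic variance fraction of the (genetic +
residual) part equals ``h2_target``; the genetic-plus-residual variance
is normalized to 1, so covariate effects are expressed on that scale.
Covariates emulate the study design: age ~ Uniform(20, 70) years,
sex ~ Bernoulli(0.5), BMI ~ Normal(27, 4^2) kg/m^2, with modest default
effects (0.01 per year of age, 0.5 for sex, 0.03 per BMI unit).

``plant_qc_violations`` injects known QC failures (high missingness,
low MAF, HWE departures, heterozygosity outliers) at recorded indices so
the QC cascade can be checked against exact expected removal counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import GenotypeMatrix, MISSING

DEFAULT_COVARIATE_EFFECTS = {"age": 0.01, "sex": 0.5, "bmi": 0.03}


@dataclass
class SimConfig:
    n_samples: int
    n_snps: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_target: float = 0.5
    n_causal: int | None = None  # None = all SNPs causal
    ld_block_size: int = 1
    ld_rho: float = 0.0
    seed: int = 0
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )

    def __post_init__(self) -> None:
        if self.n_causal is None:
            self.n_causal = self.n_snps
        low, high = self.maf_range
        if not (0.0 < low <= high <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0.0 <= self.h2_target <= 1.0:
            raise ValueError("h2_target must lie in [0, 1]")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.h2_target > 0 and self.n_causal == 0:
            raise ValueError("h2_target > 0 requires at least one causal SNP")


@dataclass
class SimTruth:
    """Ground truth of one phenotype draw, for parameter-recovery tests."""

    causal_indices: np.ndarray
    true_u: np.ndarray  # per-SNP effects on the standardized scale (0 off-causal)
    true_h2: float  # realized var(Wu) / var(Wu + eps)
    beta: dict[str, float]
    genetic_values: np.ndarray


def _simulate_haplotype(rng: np.random.Generator, n: int, thresholds: np.ndarray,
                        block: int, rho: float) -> np.ndarray:
    """One allele indicator per (individual, SNP) with copula LD blocks."""
    k = thresholds.size
    if block == 1 or rho == 0.0:
        latent = rng.standard_normal((n, k))
    else:
        latent = np.empty((n, k))
        sr, sc = np.sqrt(rho), np.sqrt(1.0 - rho)
        for start in range(0, k, block):
            width = min(block, k - start)
            shared = rng.standard_normal((n, 1))
            latent[:, start:start + width] = sr * shared + sc * rng.standard_normal((n, width))
    return (latent < thresholds).astype(np.int8)


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """HWE genotypes with per-SNP frequency drawn Uniform over maf_range."""
    rng = np.random.default_rng(cfg.seed)
    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_snps)
    thr = norm.ppf(p)
    calls = (
        _simulate_haplotype(rng, cfg.n_samples, thr, cfg.ld_block_size, cfg.ld_rho)
        + _simulate_haplotype(rng, cfg.n_samples, thr, cfg.ld_block_size, cfg.ld_rho)
    )
    samples = pd.DataFrame(
        {
            "family_id": [f"F{i:06d}" for i in range(cfg.n_samples)],
            "sample_id": [f"S{i:06d}" for i in range(cfg.n_samples)],
            "sex": "unknown",
        }
    )
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{j:07d}" for j in range(cfg.n_snps)],
            "chrom": "1",
            "pos_bp": np.arange(1, cfg.n_snps + 1, dtype=np.int64) * 1000,
            "allele1": "A",
            "allele2": "G",
        }
    )
    return GenotypeMatrix(samples=samples, snps=snps, calls=calls)


def simulate_phenotype(
    g: GenotypeMatrix, cfg: SimConfig
) -> tuple[pd.DataFrame, SimTruth]:
    """Draw covariates and a trait y = X beta + W u + eps at h2_target."""
    from .grm import standardize

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7_119_311]))
    n = g.n_samples
    age = rng.uniform(20.0, 70.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    bmi = rng.normal(27.0, 4.0, size=n)
    beta = dict(cfg.covariate_effects)
    fixed = beta.get("age", 0.0) * age + beta.get("sex", 0.0) * sex + beta.get("bmi", 0.0) * bmi

    u = np.zeros(g.n_snps)
    gvals = np.zeros(n)
    causal = np.sort(rng.choice(g.n_snps, size=cfg.n_causal, replace=False))
    if cfg.h2_target > 0.0 and cfg.n_causal > 0:
        # SNPs monomorphic in this sample carry no genetic variance and
        # cannot be standardized; they stay causal-with-zero-effect.
        from .grm import allele1_freqs

        p_causal = allele1_freqs(g.subset(snp_idx=causal))
        poly = causal[(p_causal > 0.0) & (p_causal < 1.0)]
        if poly.size == 0:
            raise ValueError("all causal SNPs are monomorphic in this sample")
        w = standardize(g.subset(snp_idx=poly)).w
        u0 = rng.standard_normal(poly.size)
        g0 = w @ u0
        var_g0 = g0.var()
        if var_g0 <= 0:
            raise ValueError("degenerate genetic values; increase n_samples or n_causal")
        scale = np.sqrt(cfg.h2_target / var_g0)
        u[poly] = u0 * scale
        gvals = g0 * scale
    sigma_e2 = 1.0 - cfg.h2_target
    eps = rng.normal(0.0, np.sqrt(sigma_e2), size=n) if sigma_e2 > 0 else np.zeros(n)
    y = fixed + gvals + eps

    denom = (gvals + eps).var()
    true_h2 = float(gvals.var() / denom) if denom > 0 else 0.0
    pheno = pd.DataFrame(
        {
            "sample_id": g.samples["sample_id"].to_numpy(),
            "trait": y,
            "age": age,
            "sex": sex,
            "bmi": bmi,
        }
    )
    truth = SimTruth(
        causal_indices=causal,
        true_u=u,
        true_h2=true_h2,
        beta=beta,
        genetic_values=gvals,
    )
    return pheno, truth


def mate_random_pairs(g: GenotypeMatrix, n_offspring: int, seed: int = 0) -> GenotypeMatrix:
    """Offspring genotypes by Mendelian sampling from random parent pairs.

    Each offspring draws two distinct parents; at every SNP each parent
    transmits allele1 with probability z/2. Appending the offspring to a
    founder panel creates parent-offspring GRM entries near 0.5, for
    tests of relatedness effects. Requires a complete (no-missing) panel.
    """
    if (g.calls < 0).any():
        raise ValueError("Mendelian sampling requires complete genotypes")
    rng = np.random.default_rng(seed)
    n, k = g.n_samples, g.n_snps
    if n < 2:
        raise ValueError("need at least two potential parents")
    p_transmit = g.calls.astype(np.float64) / 2.0
    calls = np.empty((n_offspring, k), dtype=np.int8)
    parents = np.empty((n_offspring, 2), dtype=np.int64)
    for i in range(n_offspring):
        pa, ma = rng.choice(n, size=2, replace=False)
        parents[i] = (pa, ma)
        calls[i] = (
            (rng.random(k) < p_transmit[pa]).astype(np.int8)
            + (rng.random(k) < p_transmit[ma]).astype(np.int8)
        )
    samples = pd.DataFrame(
        {
            "family_id": [f"FAM{pa:06d}_{ma:06d}" for pa, ma in parents],
            "sample_id": [f"O{i:06d}" for i in range(n_offspring)],
            "sex": "unknown",
        }
    )
    return GenotypeMatrix(samples=samples, snps=g.snps.copy(), calls=calls)


def plant_qc_violations(
    g: GenotypeMatrix, spec: dict, seed: int = 0
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Inject QC failures into a clean matrix; returns exact expected removals.

    ``spec`` keys (all optional, counts default 0):
      ``missing_snps`` (+ ``missing_rate``, default 0.3) — SNPs with planted
      missing calls; ``low_maf_snps`` (+ ``low_maf``, default 0.01) — SNPs
      redrawn at a frequency below the MAF floor; ``hwe_snps`` — SNPs redrawn
      with zero heterozygotes at p = 0.5 (chi-square = n); ``het_samples`` —
      individuals set heterozygous at every SNP.

    Planted index sets are disjoint; the returned dict maps QC step names to
    the removal counts the default cascade must report.
    """
    rng = np.random.default_rng(seed)
    n, k = g.n_samples, g.n_snps
    n_miss = int(spec.get("missing_snps", 0))
    n_lowmaf = int(spec.get("low_maf_snps", 0))
    n_hwe = int(spec.get("hwe_snps", 0))
    n_het = int(spec.get("het_samples", 0))
    miss_rate = float(spec.get("missing_rate", 0.3))
    low_maf = float(spec.get("low_maf", 0.01))

    if n_miss + n_lowmaf + n_hwe > k:
        raise ValueError("more planted SNP violations than SNPs")
    if n_het > n:
        raise ValueError("more planted sample violations than samples")
    if n_hwe and n < 40:
        raise ValueError("HWE violations at p < 1e-6 need n >= 40")

    calls = g.calls.copy()
    snp_idx = rng.permutation(k)
    miss_idx = snp_idx[:n_miss]
    lowmaf_idx = snp_idx[n_miss:n_miss + n_lowmaf]
    hwe_idx = snp_idx[n_miss + n_lowmaf:n_miss + n_lowmaf + n_hwe]
    het_idx = rng.permutation(n)[:n_het]

    # Het outliers first: the violating columns planted below overwrite a few
    # of their cells, but those columns are removed by earlier QC steps, so
    # the outliers are still all-heterozygous on every SNP the het step sees.
    for i in het_idx:
        calls[i, :] = 1  # heterozygous everywhere -> het rate 1.0
    for j in miss_idx:
        n_gone = int(np.ceil(miss_rate * n))
        if n_gone / n <= 0.2:
            raise ValueError("missing_rate too low to trip the stage-1 filter")
        calls[rng.choice(n, size=n_gone, replace=False), j] = MISSING
    for j in lowmaf_idx:
        calls[:, j] = rng.binomial(2, low_maf, size=n).astype(np.int8)
    for j in hwe_idx:
        half = n // 2
        col = np.concatenate([np.zeros(n - half, np.int8), np.full(half, 2, np.int8)])
        calls[:, j] = rng.permutation(col)

    expected = {
        "missing_stage1": n_miss,
        "missing_stage2": 0,
        "sex_check": 0,
        "maf": n_lowmaf,
        "hwe": n_hwe,
        "heterozygosity": n_het,
    }
    planted = GenotypeMatrix(samples=g.samples.copy(), snps=g.snps.copy(), calls=calls)
    return planted, expected
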