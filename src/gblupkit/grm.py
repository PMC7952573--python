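"""Genomic relationship matrix (GRM) from standardized genotypes.

Genotypes z in {0,1,2} (copies of allele1) are standardized SNP-wise to

    w_ij = (z_ij - 2 p_j) / sqrt(2 p_j (1 - p_j)),

with p_j the allele1 frequency. Off-diagonal relationships are the
cross-products A = W W' / K over K SNPs. Diagonals use the
homozygosity-based estimator

    A_ii = 1 + (1/K) sum_j [z_ij^2 - (1 + 2 p_j) z_ij + 2 p_j^2] / (2 p_j (1 - p_j)),

whose expectation is exactly 1 under Hardy-Weinberg genotype frequencies
(with the (1 - 2p) sign sometimes seen in print, the expectation is
1 + 4p^2/(1-p) per SNP, which mis-calibrates the diagonal; a regression
test pins the implemented sign). Missing genotypes standardize to w = 0,
i.e. mean imputation at 2 p_j.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GenotypeMatrix


class DegenerateSNPError(ValueError):
    """Raised when a SNP is monomorphic (p in {0, 1}) at standardization."""

    def __init__(self, snp_ids):
        self.snp_ids = list(snp_ids)
        super().__init__(
            f"{len(self.snp_ids)} SNP(s) have allele frequency 0 or 1 and cannot "
            f"be standardized: {self.snp_ids[:10]}"
        )


@dataclass
class StandardizedGenotypes:
    """Centered/scaled genotype matrix W with the frequencies that built it.

    ``source`` records whether ``freqs`` were estimated from these samples
    ("own") or supplied externally, e.g. from a training set ("training") —
    test-set standardization must reuse training frequencies to avoid
    leakage in cross-validation.
    """

    w: np.ndarray
    freqs: np.ndarray
    snp_ids: np.ndarray
    allele1: np.ndarray
    sample_ids: np.ndarray
    source: str = "own"

    @property
    def n_samples(self) -> int:
        return self.w.shape[0]

    @property
    def k_snps(self) -> int:
        return self.w.shape[1]


@dataclass
class GRM:
    """Symmetric n x n genomic relationship matrix built from K SNPs."""

    a: np.ndarray
    k_snps: int
    sample_ids: list

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.float64)
        if self.a.ndim != 2 or self.a.shape[0] != self.a.shape[1]:
            raise ValueError("GRM must be square")

    @property
    def n(self) -> int:
        return self.a.shape[0]

    def validate(self) -> None:
        if self.k_snps < 1:
            raise ValueError("GRM must be built from at least one SNP")
        if not np.allclose(self.a, self.a.T, atol=1e-12):
            raise ValueError("GRM is not symmetric")


def allele1_freqs(g: GenotypeMatrix) -> np.ndarray:
    """Per-SNP allele1 frequency p_j from non-missing calls."""
    calls = g.calls
    obs = calls >= 0
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        bad = g.snps["snp_id"].to_numpy()[n_obs == 0]
        raise ValueError(f"all-missing SNPs have undefined frequency: {bad[:10]}")
    counts = np.where(obs, calls, 0).sum(axis=0)
    return counts / (2.0 * n_obs)


def standardize(g: GenotypeMatrix, freqs: np.ndarray | None = None) -> StandardizedGenotypes:
    """Standardize genotypes; missing calls become w = 0 (mean imputation)."""
    if freqs is None:
        p = allele1_freqs(g)
        source = "own"
    else:
        p = np.asarray(freqs, dtype=np.float64)
        if p.shape != (g.n_snps,):
            raise ValueError("freqs length must equal the SNP count")
        source = "training"
    degenerate = (p <= 0.0) | (p >= 1.0)
    if degenerate.any():
        raise DegenerateSNPError(g.snps["snp_id"].to_numpy()[degenerate])
    scale = np.sqrt(2.0 * p * (1.0 - p))
    calls = g.calls.astype(np.float64)
    w = (calls - 2.0 * p) / scale
    w[g.calls < 0] = 0.0
    return StandardizedGenotypes(
        w=w,
        freqs=p,
        snp_ids=g.snps["snp_id"].to_numpy(),
        allele1=g.snps["allele1"].to_numpy(),
        sample_ids=g.samples["sample_id"].to_numpy(),
        source=source,
    )


def compute_grm(wg: StandardizedGenotypes) -> GRM:
    """GRM with WW'/K off-diagonals and homozygosity-based diagonals."""
    k = wg.k_snps
    if k == 0:
        raise ValueError("cannot compute a GRM from an empty SNP panel")
    w = wg.w
    a = w @ w.T / k
    # Yang diagonal rewritten in terms of w:
    #   [z^2 - (1+2p) z + 2p^2] / (2pq) = w^2 + w (2p-1)/sqrt(2pq) - 1,
    # so A_ii = (1/K) sum_j [w_ij^2 + w_ij (2p_j - 1)/sqrt(2 p_j q_j)].
    p = wg.freqs
    c = (2.0 * p - 1.0) / np.sqrt(2.0 * p * (1.0 - p))
    diag = (np.einsum("ij,ij->i", w, w) + w @ c) / k
    np.fill_diagonal(a, diag)
    return GRM(a=a, k_snps=k, sample_ids=list(wg.sample_ids))


def cross_product_grm(wg: StandardizedGenotypes) -> GRM:
    """Plain A = WW'/K (cross-product diagonal, VanRaden-style).

    This is the A under which the gBLUP/SNP-BLUP identities (ridge
    duality, W u_hat = g_hat) are exact; :func:`compute_grm` differs only
    in its homozygosity-based diagonal.
    """
    k = wg.k_snps
    if k == 0:
        raise ValueError("cannot compute a GRM from an empty SNP panel")
    return GRM(a=wg.w @ wg.w.T / k, k_snps=k, sample_ids=list(wg.sample_ids))


def subset_grm(
    g: GenotypeMatrix, snp_idx, freqs: np.ndarray | None = None
) -> GRM:
    """GRM restricted to a SNP subset (positional indices), K = |subset|."""
    snp_idx = np.asarray(snp_idx)
    if snp_idx.size == 0:
        raise ValueError("SNP subset for the GRM must be non-empty")
    sub = g.subset(snp_idx=snp_idx)
    f = None if freqs is None else np.asarray(freqs)[snp_idx]
    return compute_grm(standardize(sub, freqs=f))
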