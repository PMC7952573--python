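"""Genotype and sample quality control.

The cascade mirrors standard array-QC practice: a lenient missingness
pass (default 0.2) to discard junk, a strict missingness pass (default
0.02), a minor-allele-frequency floor (default 0.05), an exact
Hardy-Weinberg equilibrium test (default alpha 1e-6) and finally removal
of samples whose heterozygosity rate lies more than 3 SD from the mean.
Within each missingness stage SNPs are dropped before samples, and every
step recomputes its statistics on the current matrix. A sex-discrepancy
stage is logged as a no-op for report parity (the data model carries no
X chromosome).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .io import GenotypeMatrix


@dataclass
class QCConfig:
    missing_stage1: float = 0.2
    missing_stage2: float = 0.02
    maf_min: float = 0.05
    hwe_alpha: float = 1e-6
    het_sd: float = 3.0

    def __post_init__(self) -> None:
        for name in ("missing_stage1", "missing_stage2", "maf_min", "hwe_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.missing_stage2 > self.missing_stage1:
            raise ValueError("missing_stage2 must be <= missing_stage1")
        if self.het_sd <= 0:
            raise ValueError("het_sd must be positive")


@dataclass
class QCStep:
    name: str
    snps_removed: int = 0
    samples_removed: int = 0


@dataclass
class QCReport:
    steps: list[QCStep] = field(default_factory=list)
    initial_n: int = 0
    initial_k: int = 0
    final_n: int = 0
    final_k: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.snps_removed, s.samples_removed) for s in self.steps],
            columns=["step", "snps_removed", "samples_removed"],
        )

    def counts(self) -> dict[str, tuple[int, int]]:
        return {s.name: (s.snps_removed, s.samples_removed) for s in self.steps}

    def validate(self) -> None:
        if self.final_k != self.initial_k - sum(s.snps_removed for s in self.steps):
            raise ValueError("SNP bookkeeping inconsistent")
        if self.final_n != self.initial_n - sum(s.samples_removed for s in self.steps):
            raise ValueError("sample bookkeeping inconsistent")


class EmptyPanelError(RuntimeError):
    def __init__(self, report: QCReport):
        self.report = report
        super().__init__("QC removed every SNP; no panel remains")


def snp_missing_rate(g: GenotypeMatrix) -> np.ndarray:
    return (g.calls < 0).mean(axis=0) if g.n_samples else np.zeros(g.n_snps)


def sample_missing_rate(g: GenotypeMatrix) -> np.ndarray:
    return (g.calls < 0).mean(axis=1) if g.n_snps else np.zeros(g.n_samples)


def maf(g: GenotypeMatrix, j: int) -> float:
    """Minor allele frequency of SNP j from non-missing calls."""
    col = g.calls[:, j]
    obs = col >= 0
    n_obs = int(obs.sum())
    if n_obs == 0:
        raise ValueError(f"SNP {j} is all-missing; frequency undefined")
    p = col[obs].sum() / (2.0 * n_obs)
    return float(min(p, 1.0 - p))


def _all_maf(g: GenotypeMatrix) -> np.ndarray:
    obs = g.calls >= 0
    n_obs = obs.sum(axis=0)
    p = np.where(obs, g.calls, 0).sum(axis=0) / np.maximum(2.0 * n_obs, 1.0)
    p = np.where(n_obs > 0, p, 0.5)  # all-missing columns are caught upstream
    return np.minimum(p, 1.0 - p)


def hwe_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Sums, over heterozygote counts consistent with the observed allele
    counts, the probabilities no larger than the observed configuration's
    (Wigginton-style enumeration). Monomorphic SNPs return p = 1.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    rare = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    # P(het = h | n, rare) proportional to 2^h / (h! ((rare-h)/2)! (n-(rare+h)/2)!)
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1.0)
        - gammaln((rare - hets) / 2.0 + 1.0)
        - gammaln(n - (rare + hets) / 2.0 + 1.0)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def hwe_chi2(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """One-df chi-square HWE test (fallback for very large panels)."""
    n = n_hom1 + n_het + n_hom2
    p = (2 * n_hom1 + n_het) / (2.0 * n)
    if p in (0.0, 1.0):
        return 1.0
    q = 1.0 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_hom1, n_het, n_hom2], dtype=float)
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2.sf(stat, df=1))


def _hwe_pvalues(g: GenotypeMatrix) -> np.ndarray:
    calls = g.calls
    out = np.empty(g.n_snps)
    for j in range(g.n_snps):
        col = calls[:, j]
        col = col[col >= 0]
        out[j] = hwe_test(int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum()))
    return out


def heterozygosity_rate(g: GenotypeMatrix) -> np.ndarray:
    """Per-sample het rate: n_het / n_nonmissing."""
    het = (g.calls == 1).sum(axis=1)
    obs = (g.calls >= 0).sum(axis=1)
    return het / np.maximum(obs, 1)


def run_qc(g: GenotypeMatrix, cfg: QCConfig | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the full QC cascade; returns the filtered matrix and a report."""
    cfg = cfg or QCConfig()
    if g.n_snps == 0 or g.n_samples == 0:
        raise ValueError("QC requires a non-empty genotype matrix")
    report = QCReport(initial_n=g.n_samples, initial_k=g.n_snps)
    cur = g

    def drop(step: QCStep, snp_keep=None, sample_keep=None):
        nonlocal cur
        if snp_keep is not None:
            step.snps_removed += int((~snp_keep).sum())
            cur = cur.subset(snp_idx=np.flatnonzero(snp_keep))
        if sample_keep is not None:
            step.samples_removed += int((~sample_keep).sum())
            cur = cur.subset(sample_idx=np.flatnonzero(sample_keep))
        if cur.n_snps == 0:
            report.steps.append(step)
            report.final_n, report.final_k = cur.n_samples, 0
            raise EmptyPanelError(report)

    for name, thr in (("missing_stage1", cfg.missing_stage1), ("missing_stage2", cfg.missing_stage2)):
        step = QCStep(name)
        drop(step, snp_keep=snp_missing_rate(cur) <= thr)
        drop(step, sample_keep=sample_missing_rate(cur) <= thr)
        report.steps.append(step)

    report.steps.append(QCStep("sex_check"))  # no-op: no X chromosome in the model

    step = QCStep("maf")
    drop(step, snp_keep=_all_maf(cur) >= cfg.maf_min)
    report.steps.append(step)

    step = QCStep("hwe")
    if cfg.hwe_alpha > 0:
        drop(step, snp_keep=_hwe_pvalues(cur) >= cfg.hwe_alpha)
    report.steps.append(step)

    step = QCStep("heterozygosity")
    het = heterozygosity_rate(cur)
    mu, sd = het.mean(), het.std(ddof=0)
    keep = np.abs(het - mu) <= cfg.het_sd * sd if sd > 0 else np.ones(cur.n_samples, bool)
    drop(step, sample_keep=keep)
    report.steps.append(step)

    report.final_n, report.final_k = cur.n_samples, cur.n_snps
    report.validate()
    return cur, report
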