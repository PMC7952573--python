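"""Phenotype preparation, population-structure PCs, and per-SNP GWAS.

Trait handling follows lipid-panel convention: LDL-C by the Friedewald
equation (mg/dL), triglycerides analysed on the natural-log scale, and
age/sex/BMI covariates chosen by bidirectional stepwise selection under
AIC. Population structure is summarized by the top eigenvectors of the
GRM and entered as fixed covariates (20 by default, configurable down
for small simulations). The association scan itself is ordinary least
squares of the trait on [1, covariates, PCs, allele count], with a
two-sided t test on the allele-count coefficient; its p-values provide
the ranking that drives SNP-subset selection downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .grm import GRM
from .io import GenotypeMatrix

CANDIDATE_COVARIATES = ("age", "sex", "bmi")


class FriedewaldWarning(UserWarning):
    """TG > 400 mg/dL: the Friedewald LDL-C approximation is unreliable."""


def friedewald_ldl(tc, hdl, tg):
    """LDL-C = TC - HDL-C - TG/5, all in mg/dL (scalar or array)."""
    tc = np.asarray(tc, dtype=np.float64)
    hdl = np.asarray(hdl, dtype=np.float64)
    tg = np.asarray(tg, dtype=np.float64)
    if (tc < 0).any() or (hdl < 0).any() or (tg < 0).any():
        raise ValueError("lipid concentrations must be non-negative")
    if (tg > 400).any():
        warnings.warn(
            "TG above 400 mg/dL: Friedewald LDL-C is unreliable", FriedewaldWarning
        )
    out = tc - hdl - tg / 5.0
    return float(out) if out.ndim == 0 else out


def log_tg(tg):
    """Natural log of triglycerides; corrects the right-skewed distribution."""
    tg = np.asarray(tg, dtype=np.float64)
    if (tg <= 0).any():
        raise ValueError("TG must be positive for the log transform")
    out = np.log(tg)
    return float(out) if out.ndim == 0 else out


@dataclass
class CovariateModel:
    selected: tuple[str, ...]
    n_pcs: int = 20
    coefficients: dict[str, float] = field(default_factory=dict)
    aic: float = float("nan")

    def design(self, pheno: pd.DataFrame) -> np.ndarray:
        """[1, selected covariates] design matrix for the given table."""
        cols = [np.ones(len(pheno))]
        cols += [pheno[c].to_numpy(dtype=np.float64) for c in self.selected]
        return np.column_stack(cols)


def stepwise_covariates(
    y, covariates: pd.DataFrame, candidates=CANDIDATE_COVARIATES, n_pcs: int = 20
) -> CovariateModel:
    """Bidirectional stepwise covariate selection by AIC, from the full model."""
    y = np.asarray(y, dtype=np.float64)
    if np.ptp(y) == 0:
        raise ValueError("constant trait; covariate selection is degenerate")
    candidates = [c for c in candidates if c in covariates.columns]
    if len(y) <= len(candidates) + 2:
        raise ValueError("too few samples for stepwise selection")

    def fit(subset):
        x = sm.add_constant(
            covariates[list(subset)].to_numpy(dtype=np.float64), has_constant="add"
        )
        return sm.OLS(y, x).fit()

    current = tuple(candidates)
    best = fit(current)
    improved = True
    while improved:
        improved = False
        moves = [tuple(c for c in current if c != drop) for drop in current]
        moves += [current + (add,) for add in candidates if add not in current]
        for subset in moves:
            res = fit(subset)
            if res.aic < best.aic - 1e-9:
                best, current, improved = res, subset, True
    coeffs = {"const": float(best.params[0])}
    coeffs.update({c: float(b) for c, b in zip(current, best.params[1:])})
    return CovariateModel(
        selected=current, n_pcs=n_pcs, coefficients=coeffs, aic=float(best.aic)
    )


def grm_pcs(a: GRM, n_pcs: int) -> np.ndarray:
    """Top eigenvectors of the GRM, descending eigenvalue order, unit norm.

    Sign convention: the largest-magnitude loading of each PC is positive.
    """
    n = a.n
    if n_pcs > n:
        raise ValueError(f"n_pcs={n_pcs} exceeds sample count {n}")
    if n_pcs == 0:
        return np.empty((n, 0))
    vals, vecs = np.linalg.eigh(a.a)
    order = np.argsort(vals)[::-1][:n_pcs]
    pcs = vecs[:, order]
    for j in range(pcs.shape[1]):
        if pcs[np.argmax(np.abs(pcs[:, j])), j] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs


def gwas_scan(
    g: GenotypeMatrix,
    y,
    covariates: np.ndarray | pd.DataFrame | None = None,
    pcs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-SNP OLS association scan.

    The model per SNP j is y ~ 1 + covariates + PCs + z_j; reported are the
    allele1-dosage effect, its SE, t statistic, two-sided p, and the sample
    count used. Samples missing z_j are dropped for that SNP (casewise
    deletion). Monomorphic SNPs get p = 1 and ``flag = "monomorphic"``.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    n = y.size
    if n != g.n_samples:
        raise ValueError("phenotype length does not match the genotype matrix")
    parts = [np.ones((n, 1))]
    if covariates is not None:
        cv = covariates.to_numpy(dtype=np.float64) if hasattr(covariates, "to_numpy") else np.asarray(covariates, dtype=np.float64)
        if cv.ndim == 1:
            cv = cv[:, None]
        parts.append(cv)
    if pcs is not None and pcs.shape[1] > 0:
        parts.append(np.asarray(pcs, dtype=np.float64))
    c = np.column_stack(parts)
    p_cov = c.shape[1]

    beta = np.full(g.n_snps, np.nan)
    se = np.full(g.n_snps, np.nan)
    tstat = np.full(g.n_snps, np.nan)
    pval = np.ones(g.n_snps)
    n_used = np.full(g.n_snps, n, dtype=np.int64)
    flag = np.array([""] * g.n_snps, dtype=object)

    calls = g.calls
    has_missing = (calls < 0).any(axis=0)
    complete = np.flatnonzero(~has_missing)

    if complete.size:
        q, _ = np.linalg.qr(c)
        z = calls[:, complete].astype(np.float64)
        zr = z - q @ (q.T @ z)
        yr = y - q @ (q.T @ y)
        zz = np.einsum("ij,ij->j", zr, zr)
        poly = zz > 1e-12 * n
        df = n - p_cov - 1
        b = np.zeros(complete.size)
        b[poly] = (zr[:, poly].T @ yr) / zz[poly]
        rss = yr @ yr - b**2 * zz
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.sqrt(np.maximum(rss, 0.0) / df / zz)
            t = b / s
        idx = complete[poly]
        beta[idx] = b[poly]
        se[idx] = s[poly]
        tstat[idx] = t[poly]
        pval[idx] = 2.0 * stats.t.sf(np.abs(t[poly]), df)
        flag[complete[~poly]] = "monomorphic"

    for j in np.flatnonzero(has_missing):
        keep = calls[:, j] >= 0
        nj = int(keep.sum())
        n_used[j] = nj
        zj = calls[keep, j].astype(np.float64)
        if nj <= p_cov + 1 or np.ptp(zj) == 0:
            flag[j] = "monomorphic" if nj and np.ptp(zj) == 0 else "insufficient_n"
            continue
        x = np.column_stack([c[keep], zj])
        coef, _, rank, _ = np.linalg.lstsq(x, y[keep], rcond=None)
        if rank < x.shape[1]:
            flag[j] = "collinear"
            continue
        resid = y[keep] - x @ coef
        df = nj - x.shape[1]
        sigma2 = resid @ resid / df
        xtx_inv = np.linalg.inv(x.T @ x)
        sj = np.sqrt(sigma2 * xtx_inv[-1, -1])
        beta[j] = coef[-1]
        se[j] = sj
        tstat[j] = coef[-1] / sj
        pval[j] = 2.0 * stats.t.sf(abs(tstat[j]), df)

    return pd.DataFrame(
        {
            "snp_id": g.snps["snp_id"].to_numpy(),
            "chrom": g.snps["chrom"].to_numpy(),
            "pos_bp": g.snps["pos_bp"].to_numpy(),
            "allele1": g.snps["allele1"].to_numpy(),
            "allele2": g.snps["allele2"].to_numpy(),
            "beta": beta,
            "se": se,
            "t_stat": tstat,
            "p_value": pval,
            "n_used": n_used,
            "flag": flag,
        }
    )
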