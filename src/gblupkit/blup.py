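"""gBLUP genetic values, SNP-effect back-solving, and polygenic scoring.

With variance components in hand, generalized least squares gives the
fixed effects and the BLUP of the total genetic values:

    beta_hat = (X'V^-1 X)^-1 X'V^-1 y,
    g_hat    = A sigma_g^2 V^-1 (y - X beta_hat),   V = A sigma_g^2 + I sigma_e^2.

Per-SNP effects on the standardized scale are recovered as
u_hat = W' A^-1 g_hat / K (with A = WW'/K this is W'(WW')^-1 g_hat, the
minimum-norm pre-image of g_hat), and converted to the allele-count
scale by u*_j = u_hat_j / sqrt(2 p_j (1 - p_j)). Held-out individuals
are scored either as w_test . u_hat (test genotypes standardized with
TRAINING frequencies) or as z_test . u*_j; the two differ per individual
by a constant, so correlations with phenotype are identical. Scores are
sums over SNPs, not averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grm import GRM, StandardizedGenotypes
from .io import GenotypeMatrix
from .varcomp import VarianceComponents


class AlleleMismatchError(ValueError):
    def __init__(self, snp_ids):
        self.snp_ids = list(snp_ids)
        super().__init__(
            f"allele coding mismatch between training effects and test panel "
            f"for {len(self.snp_ids)} SNP(s): {self.snp_ids[:10]}"
        )


@dataclass
class BlupFit:
    """Fitted gBLUP: fixed effects, genetic values, optional SNP effects."""

    beta_hat: np.ndarray
    g_hat: np.ndarray
    sample_ids: np.ndarray
    sigma_g2: float
    sigma_e2: float
    u_hat: np.ndarray | None = None  # standardized scale, length K
    u_star: np.ndarray | None = None  # allele-count scale
    freqs: np.ndarray | None = None  # training allele1 frequencies
    snp_ids: np.ndarray | None = None
    allele1: np.ndarray | None = None


def fit_blup(y, x, a: GRM, vc: VarianceComponents, *, eig=None) -> BlupFit:
    """GLS fixed effects and BLUP genetic values on the training set.

    Pass a precomputed ``eig = (eigenvalues, eigenvectors)`` of A to
    reuse the decomposition the REML fit already paid for; V-solves then
    cost O(n^2) instead of O(n^3).
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    n = y.size
    if eig is not None:
        d, u = eig
        vdiag = vc.sigma_g2 * np.maximum(d, 0.0) + vc.sigma_e2
        solve_v = lambda z: u @ ((u.T @ z).T / vdiag).T
        mul_a = lambda z: u @ ((u.T @ z).T * np.maximum(d, 0.0)).T
    else:
        v = vc.sigma_g2 * a.a + vc.sigma_e2 * np.eye(n)
        solve_v = lambda z: np.linalg.solve(v, z)
        mul_a = lambda z: a.a @ z
    vinv_x = solve_v(x)
    vinv_y = solve_v(y)
    xtvx = x.T @ vinv_x
    if np.linalg.matrix_rank(xtvx) < x.shape[1]:
        raise np.linalg.LinAlgError("X'V^-1 X is singular")
    beta = np.linalg.solve(xtvx, x.T @ vinv_y)
    resid = y - x @ beta
    g_hat = vc.sigma_g2 * mul_a(solve_v(resid))
    return BlupFit(
        beta_hat=beta,
        g_hat=g_hat,
        sample_ids=np.asarray(a.sample_ids),
        sigma_g2=vc.sigma_g2,
        sigma_e2=vc.sigma_e2,
    )


def backsolve_snp_effects(
    fit: BlupFit, wg: StandardizedGenotypes, *, rcond: float = 1e-10
) -> BlupFit:
    """Fill u_hat = W'A^-1 g_hat / K and u* on the allele-count scale.

    A is rebuilt here as WW'/K exactly (cross-product diagonal, not the
    homozygosity-based one) so that W u_hat reproduces g_hat whenever
    g_hat lies in the column space of W. With own-frequency
    standardization A is always rank-deficient (column-centered W puts
    the all-ones vector in its null space), so A^-1 is taken as the
    eigendecomposition pseudo-inverse: eigenvalues below ``rcond`` times
    the largest are dropped, giving the minimum-norm pre-image of the
    projection of g_hat onto col(W).
    """
    w = wg.w
    k = wg.k_snps
    a = w @ w.T / k
    g_hat = fit.g_hat
    vals, vecs = np.linalg.eigh(a)
    keep = vals > rcond * vals.max()
    sol = vecs[:, keep] @ ((vecs[:, keep].T @ g_hat) / vals[keep])
    fit.u_hat = w.T @ sol / k
    scale = np.sqrt(2.0 * wg.freqs * (1.0 - wg.freqs))
    fit.u_star = fit.u_hat / scale
    fit.freqs = wg.freqs
    fit.snp_ids = wg.snp_ids
    fit.allele1 = wg.allele1
    return fit


def _align_test_calls(g_test: GenotypeMatrix, fit: BlupFit) -> np.ndarray:
    """Test allele1-dosages aligned to the training SNP order/orientation."""
    test_idx = {s: j for j, s in enumerate(g_test.snps["snp_id"])}
    missing_ids = [s for s in fit.snp_ids if s not in test_idx]
    if missing_ids:
        raise ValueError(f"test panel lacks {len(missing_ids)} training SNPs: {missing_ids[:10]}")
    cols = np.array([test_idx[s] for s in fit.snp_ids])
    a1 = g_test.snps["allele1"].to_numpy()[cols]
    a2 = g_test.snps["allele2"].to_numpy()[cols]
    same = a1 == fit.allele1
    flipped = a2 == fit.allele1
    bad = ~(same | flipped)
    if bad.any():
        raise AlleleMismatchError(np.asarray(fit.snp_ids)[bad])
    z = g_test.calls[:, cols].astype(np.float64)
    miss = g_test.calls[:, cols] < 0
    z[:, flipped] = 2.0 - z[:, flipped]  # count training allele1 copies
    z[miss] = np.nan
    return z


def score_individuals(
    g_test: GenotypeMatrix, fit: BlupFit, mode: str = "standardized"
) -> np.ndarray:
    """Polygenic score of test individuals, g_hat_test = w_test . u_hat.

    ``mode="standardized"`` standardizes test genotypes with the training
    frequencies and applies u_hat; ``mode="allele_count"`` applies u* to
    raw dosages. Missing test genotypes are mean-imputed (w = 0 /
    z = 2 p_j).
    """
    if fit.u_hat is None:
        raise ValueError("call backsolve_snp_effects before scoring")
    z = _align_test_calls(g_test, fit)
    p = fit.freqs
    if mode == "standardized":
        w = (z - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
        w = np.nan_to_num(w, nan=0.0)
        return w @ fit.u_hat
    if mode == "allele_count":
        z = np.where(np.isnan(z), 2.0 * p, z)
        return z @ fit.u_star
    raise ValueError(f"unknown scoring mode {mode!r}")
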