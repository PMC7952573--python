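"""BLUP genetic values, SNP-effect back-solving, polygenic scoring."""

import numpy as np
import pandas as pd
import pytest

import gblupkit as gk
from gblupkit.blup import AlleleMismatchError, BlupFit
from gblupkit.grm import cross_product_grm
from gblupkit.varcomp import VarianceComponents


def _vc(sg, se):
    return VarianceComponents(sigma_g2=sg, sigma_e2=se, h2=sg / (sg + se) if sg + se else 0.0,
                              se_h2=0.0, loglik=0.0, n_iter=0, converged=True)


def _random_instance(seed, n=30, k=120, external_freqs=True):
    """Genotypes + trait; external freqs keep W un-centered (full-rank A)."""
    rng = np.random.default_rng(seed)
    cfg = gk.SimConfig(n_samples=n, n_snps=k, seed=seed, h2_target=0.5)
    g = gk.simulate_genotypes(cfg)
    freqs = rng.uniform(0.2, 0.8, size=k) if external_freqs else None
    wg = gk.standardize(g, freqs=freqs)
    y = rng.normal(size=n)
    x = np.column_stack([np.ones(n), rng.normal(size=n)])
    return g, wg, y, x


class TestFitBlup:
    def test_zero_genetic_variance_gives_zero_blup(self):
        g, wg, y, x = _random_instance(1)
        a = cross_product_grm(wg)
        fit = gk.fit_blup(y, x, a, _vc(0.0, 1.0))
        assert np.allclose(fit.g_hat, 0.0)

    def test_noiseless_limit_recovers_residual(self):
        g, wg, y, x = _random_instance(2)
        a = cross_product_grm(wg)  # k > n, external freqs -> full rank
        fit = gk.fit_blup(y, x, a, _vc(1.0, 1e-12))
        assert np.allclose(fit.g_hat, y - x @ fit.beta_hat, atol=1e-6)

    def test_matches_henderson_mme(self):
        """g_hat solves Henderson's mixed-model equations (20 x 50)."""
        g, wg, y, x = _random_instance(3, n=20, k=50)
        a = cross_product_grm(wg)
        sg, se = 0.7, 0.4
        fit = gk.fit_blup(y, x, a, _vc(sg, se))
        lam = se / sg
        ainv = np.linalg.inv(a.a)
        top = np.hstack([x.T @ x, x.T])
        bottom = np.hstack([x, np.eye(20) + lam * ainv])
        sol = np.linalg.solve(np.vstack([top, bottom]), np.r_[x.T @ y, y])
        assert np.allclose(fit.beta_hat, sol[: x.shape[1]], atol=1e-8)
        assert np.allclose(fit.g_hat, sol[x.shape[1]:], atol=1e-8)

    def test_eig_shortcut_matches_direct_solve(self):
        from scipy.linalg import eigh

        g, wg, y, x = _random_instance(8)
        a = cross_product_grm(wg)
        vc = _vc(0.6, 0.5)
        direct = gk.fit_blup(y, x, a, vc)
        viaeig = gk.fit_blup(y, x, a, vc, eig=eigh(a.a))
        assert np.allclose(direct.g_hat, viaeig.g_hat, atol=1e-9)
        assert np.allclose(direct.beta_hat, viaeig.beta_hat, atol=1e-9)


class TestBacksolve:
    def test_zero_ghat_gives_zero_effects(self):
        g, wg, y, x = _random_instance(4)
        a = cross_product_grm(wg)
        fit = gk.fit_blup(y, x, a, _vc(0.0, 1.0))
        gk.backsolve_snp_effects(fit, wg)
        assert np.allclose(fit.u_hat, 0.0)
        assert np.allclose(fit.u_star, 0.0)

    def test_projection_identity_when_k_exceeds_n(self):
        """W u_hat reproduces g_hat within 1e-8 (k > n, g_hat in col(W))."""
        for seed in range(5):
            g, wg, y, x = _random_instance(10 + seed, n=30, k=120)
            a = cross_product_grm(wg)
            vc = _vc(0.8, 0.3)
            fit = gk.fit_blup(y, x, a, vc)
            gk.backsolve_snp_effects(fit, wg)
            assert np.abs(wg.w @ fit.u_hat - fit.g_hat).max() < 1e-8

    def test_ridge_duality(self):
        """u_hat equals the SNP-BLUP ridge solution with lam = K se/sg
        within 1e-6, with own-frequency (rank-deficient) A included."""
        for seed, own in [(20, False), (21, True), (22, False)]:
            g, wg, y, x = _random_instance(seed, n=40, k=90,
                                           external_freqs=not own)
            a = cross_product_grm(wg)
            sg, se = 0.9, 0.45
            fit = gk.fit_blup(y, x, a, _vc(sg, se))
            gk.backsolve_snp_effects(fit, wg)
            lam = wg.k_snps * se / sg
            resid = y - x @ fit.beta_hat
            ridge = np.linalg.solve(wg.w.T @ wg.w + lam * np.eye(wg.k_snps),
                                    wg.w.T @ resid)
            assert np.abs(ridge - fit.u_hat).max() < 1e-6

    def test_u_star_rescaling(self):
        g, wg, y, x = _random_instance(5)
        a = cross_product_grm(wg)
        fit = gk.fit_blup(y, x, a, _vc(0.5, 0.5))
        gk.backsolve_snp_effects(fit, wg)
        assert np.allclose(fit.u_star, fit.u_hat / np.sqrt(2 * wg.freqs * (1 - wg.freqs)))


class TestScoring:
    @staticmethod
    def _fit_with_effects(u_star, freqs, snp_ids, allele1):
        scale = np.sqrt(2 * freqs * (1 - freqs))
        return BlupFit(beta_hat=np.zeros(1), g_hat=np.zeros(1), sample_ids=np.array(["t"]),
                       sigma_g2=1.0, sigma_e2=1.0, u_hat=np.asarray(u_star) * scale,
                       u_star=np.asarray(u_star, dtype=float), freqs=freqs,
                       snp_ids=np.asarray(snp_ids), allele1=np.asarray(allele1))

    @staticmethod
    def _panel(calls, allele1=("A", "A"), allele2=("G", "G")):
        calls = np.asarray(calls, dtype=np.int8)
        n, k = calls.shape
        samples = pd.DataFrame({"family_id": "F", "sample_id": [f"I{i}" for i in range(n)], "sex": "unknown"})
        snps = pd.DataFrame({"snp_id": [f"rs{j}" for j in range(k)], "chrom": "1",
                             "pos_bp": np.arange(1, k + 1),
                             "allele1": list(allele1), "allele2": list(allele2)})
        return gk.GenotypeMatrix(samples=samples, snps=snps, calls=calls)

    def test_allele_count_dot_product(self):
        fit = self._fit_with_effects([1.0, -0.5], np.array([0.5, 0.5]),
                                     ["rs0", "rs1"], ["A", "A"])
        scores = gk.score_individuals(self._panel([[2, 1]]), fit, mode="allele_count")
        assert scores[0] == pytest.approx(1.5)

    def test_mean_genotype_scores_zero_standardized(self):
        fit = self._fit_with_effects([1.0, 2.0], np.array([0.5, 0.5]),
                                     ["rs0", "rs1"], ["A", "A"])
        scores = gk.score_individuals(self._panel([[1, 1]]), fit)
        assert scores[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_scoring_modes_perfectly_correlated(self):
        """Standardized and allele-count scores differ per individual by a
        constant; Pearson r = 1 within 1e-10."""
        for seed in range(5):
            g, wg, y, x = _random_instance(30 + seed, n=60, k=80)
            a = cross_product_grm(wg)
            fit = gk.fit_blup(y, x, a, _vc(0.6, 0.6))
            gk.backsolve_snp_effects(fit, wg)
            cfg = gk.SimConfig(n_samples=50, n_snps=80, seed=900 + seed)
            g_test = gk.simulate_genotypes(cfg)
            s1 = gk.score_individuals(g_test, fit, mode="standardized")
            s2 = gk.score_individuals(g_test, fit, mode="allele_count")
            assert abs(np.corrcoef(s1, s2)[0, 1] - 1.0) < 1e-10

    def test_allele_flip_invariance(self):
        """Swapping allele1/allele2 in the test bim (and the dosage with it)
        leaves scores unchanged."""
        rng = np.random.default_rng(77)
        fit = self._fit_with_effects(rng.normal(size=2), np.array([0.3, 0.6]),
                                     ["rs0", "rs1"], ["A", "A"])
        calls = rng.integers(0, 3, size=(25, 2))
        straight = self._panel(calls)
        flipped = self._panel(np.column_stack([calls[:, 0], 2 - calls[:, 1]]),
                              allele1=("A", "G"), allele2=("G", "A"))
        s1 = gk.score_individuals(straight, fit)
        s2 = gk.score_individuals(flipped, fit)
        assert np.allclose(s1, s2, atol=1e-12)

    def test_unmatchable_alleles_raise(self):
        fit = self._fit_with_effects([1.0, 1.0], np.array([0.5, 0.5]),
                                     ["rs0", "rs1"], ["A", "T"])
        with pytest.raises(AlleleMismatchError):
            gk.score_individuals(self._panel([[1, 1]]), fit)

    def test_missing_test_genotype_mean_imputed(self):
        fit = self._fit_with_effects([1.0, 1.0], np.array([0.25, 0.25]),
                                     ["rs0", "rs1"], ["A", "A"])
        scores = gk.score_individuals(self._panel([[-1, -1]]), fit)
        assert scores[0] == pytest.approx(0.0, abs=1e-12)
        sc = gk.score_individuals(self._panel([[-1, -1]]), fit, mode="allele_count")
        assert sc[0] == pytest.approx(2 * 0.25 * 2)


def test_end_to_end_noiseless_prediction():
    """h2=1, k < n: predicted genetic values of held-out individuals track
    the true ones with r > 0.99."""
    cfg = gk.SimConfig(n_samples=400, n_snps=150, seed=55, h2_target=1.0)
    g = gk.simulate_genotypes(cfg)
    pheno, truth = gk.simulate_phenotype(g, cfg)
    train, test = np.arange(300), np.arange(300, 400)
    g_tr, g_te = g.subset(sample_idx=train), g.subset(sample_idx=test)
    y = pheno["trait"].to_numpy()[train]
    x = np.column_stack([np.ones(300), pheno[["age", "sex", "bmi"]].to_numpy()[train]])
    wg = gk.standardize(g_tr)
    a = gk.compute_grm(wg)
    vc = gk.reml_ai(y, x, a)
    fit = gk.fit_blup(y, x, a, vc)
    gk.backsolve_snp_effects(fit, wg)
    pred = gk.score_individuals(g_te, fit)
    assert np.corrcoef(pred, truth.genetic_values[test])[0, 1] > 0.99
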