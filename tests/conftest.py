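import numpy as np
import pandas as pd
import pytest

from gblupkit.io import GenotypeMatrix


def make_random_genotypes(rng: np.random.Generator, n: int, k: int,
                          missing_rate: float = 0.0) -> GenotypeMatrix:
    """Arbitrary (not HWE) genotype matrix for format round-trip tests."""
    calls = rng.integers(0, 3, size=(n, k)).astype(np.int8)
    if missing_rate > 0:
        calls[rng.random((n, k)) < missing_rate] = -1
    samples = pd.DataFrame(
        {
            "family_id": [f"F{i}" for i in range(n)],
            "sample_id": [f"I{i}" for i in range(n)],
            "sex": rng.choice(["male", "female", "unknown"], size=n),
        }
    )
    snps = pd.DataFrame(
        {
            "snp_id": [f"rs{j}" for j in range(k)],
            "chrom": rng.choice(["1", "2", "X1"], size=k).astype(str),
            "pos_bp": np.sort(rng.integers(1, 10**7, size=k)),
            "allele1": ["A"] * k,
            "allele2": ["G"] * k,
        }
    )
    return GenotypeMatrix(samples=samples, snps=snps, calls=calls)


@pytest.fixture(scope="session")
def sim_small():
    """A clean simulated panel shared by fast unit tests (n=300, k=400)."""
    import gblupkit as gk

    cfg = gk.SimConfig(n_samples=300, n_snps=400, seed=11, h2_target=0.5,
                       maf_range=(0.1, 0.5))
    g = gk.simulate_genotypes(cfg)
    pheno, truth = gk.simulate_phenotype(g, cfg)
    return g, pheno, truth, cfg
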