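import numpy as np
import pytest

import etgwas


@pytest.fixture(scope="session")
def small_panel():
    """A small structured panel with one common and one rare causal SNP,
    modest missingness, used across module tests."""
    cfg = etgwas.SimConfig(
        n_accessions=120,
        n_snps=600,
        n_subpops=3,
        fst=0.1,
        causal=[
            etgwas.CausalSpec(index=200, effect=1.2, target_freq=0.30),
            etgwas.CausalSpec(index=450, effect=3.0, target_freq=0.04, rare=True),
        ],
        h2=0.4,
        subpop_shift=(-0.3, 0.0, 0.3),
        missing_rate=0.02,
        seed=11,
    )
    geno, truth = etgwas.simulate_genotypes(cfg)
    pheno = etgwas.simulate_phenotype(geno, truth, cfg)
    return cfg, geno, pheno, truth


@pytest.fixture()
def toy_geno():
    """Four accessions x three sites with hand-set dosages."""
    sites = [
        etgwas.VariantSite("1", 100, "s1", "A", "G"),
        etgwas.VariantSite("1", 200, "s2", "C", "T"),
        etgwas.VariantSite("1", 300, "s3", "G", "A"),
    ]
    calls = np.array(
        [
            [0, 2, 0],
            [1, 1, 1],
            [2, 0, 2],
            [0, 2, etgwas.MISSING],
        ],
        dtype=np.int16,
    )
    return etgwas.GenotypeMatrix(sites, ["a1", "a2", "a3", "a4"], calls)
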