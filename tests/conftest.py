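import numpy as np
import pandas as pd
import pytest

from pathmeld.core_io import GeneSetCollection, GenotypeStudy


def make_study(dosage, phenotype, chrom=None, pos=None):
    """GenotypeStudy from a plain dosage matrix (helper for toys)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_snps = dosage.shape[1]
    snp_table = pd.DataFrame(
        {
            "id": [f"rs{j + 1}" for j in range(n_snps)],
            "chrom": chrom if chrom is not None else ["1"] * n_snps,
            "pos": pos if pos is not None else 1000 * np.arange(1, n_snps + 1),
            "a1": "A",
            "a2": "G",
        }
    )
    return GenotypeStudy(
        dosage=dosage,
        phenotype=np.asarray(phenotype, dtype=int),
        sample_ids=[f"s{i + 1}" for i in range(dosage.shape[0])],
        snp_table=snp_table,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def null_study(rng):
    """Phenotype independent of all genotypes (global null), no LD."""
    n, m = 120, 60
    freq = rng.uniform(0.2, 0.5, size=m)
    dosage = rng.binomial(2, freq, size=(n, m)).astype(np.int8)
    phenotype = np.array([0, 1] * (n // 2))
    return make_study(dosage, phenotype)


@pytest.fixture
def tiny_sets():
    return GeneSetCollection(
        {"SET_A": frozenset({"G1", "G2"}), "SET_B": frozenset({"G3", "G4", "G5"})}
    )
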