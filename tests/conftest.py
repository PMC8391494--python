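import numpy as np
import pytest

from gpmine.containers import GenotypeMatrix, VariantInfo
from gpmine.datasets import opioid_counts, opioid_genotypes


@pytest.fixture
def opioid():
    """294-individual two-variant dataset of the opioid worked example."""
    return opioid_genotypes()


@pytest.fixture
def opioid_table():
    return opioid_counts()


def make_random_matrix(rng, n_individuals, n_variants, missing_rate=0.0):
    """Random genotype matrix: independent variants at random MAFs."""
    mafs = rng.uniform(0.05, 0.5, n_variants)
    cols = []
    for q in mafs:
        probs = [(1 - q) ** 2, 2 * q * (1 - q), q * q]
        cols.append(rng.choice([1, 2, 3], size=n_individuals, p=probs))
    genotypes = np.column_stack(cols).astype(np.int8)
    if missing_rate:
        genotypes[rng.random(genotypes.shape) < missing_rate] = 0
    phenotype = rng.permutation(
        np.r_[
            np.ones(n_individuals // 2, dtype=np.int8),
            np.zeros(n_individuals - n_individuals // 2, dtype=np.int8),
        ]
    )
    variants = [
        VariantInfo(id=f"snp{j}", chromosome="1", position=j + 1)
        for j in range(n_variants)
    ]
    return GenotypeMatrix(
        genotypes=genotypes,
        phenotype=phenotype,
        variants=variants,
        individual_ids=[f"i{k}" for k in range(n_individuals)],
    )


@pytest.fixture
def random_matrix_factory():
    return make_random_matrix
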