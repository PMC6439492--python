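import numpy as np
import pytest

from kelpabc.datasets import (
    MsatGenotypeMatrix,
    PopulationDataset,
    PopulationPartition,
    SequenceAlignment,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def tiny_alignment():
    """8 sequences, 3 haplotypes, two populations in two groups."""
    seqs = [
        "ACGTACGTAC",
        "ACGTACGTAC",
        "ACGTACGAAC",
        "ACGTACGTAC",
        "TCGTACGTAC",
        "TCGTACGTAC",
        "TCGTACGTAC",
        "ACGTACGAAC",
    ]
    ids = [f"i{k}" for k in range(8)]
    return SequenceAlignment(seqs, ids)


@pytest.fixture
def tiny_partition():
    return PopulationPartition(
        {f"i{k}": ("popA" if k < 4 else "popB") for k in range(8)},
        {"popA": "G1", "popB": "G2"},
    )


def random_genotypes(
    rng, n_ind: int, n_loci: int, n_alleles: int = 5, missing_rate: float = 0.0
) -> MsatGenotypeMatrix:
    alleles = rng.integers(10, 10 + n_alleles, size=(n_ind, n_loci, 2))
    if missing_rate > 0:
        miss = rng.random((n_ind, n_loci)) < missing_rate
        alleles[miss] = -1
    return MsatGenotypeMatrix(alleles, [f"i{k}" for k in range(n_ind)])


@pytest.fixture
def tiny_dataset(rng, tiny_alignment, tiny_partition):
    geno = random_genotypes(rng, 8, 4)
    return PopulationDataset(
        genotypes=geno, partition=tiny_partition, sequences=tiny_alignment
    )
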