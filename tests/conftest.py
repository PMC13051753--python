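import numpy as np
import pytest

from msatkin.genotype_io import GenotypeTable, LocusFrequencies


def single_locus_table(locus: str, genotypes: list[tuple[int, int]]) -> GenotypeTable:
    """Build a one-locus table from a list of allele pairs (0,0 = missing)."""
    arr = np.array(genotypes, dtype=np.int64).reshape(len(genotypes), 1, 2)
    ids = [f"I{i:02d}" for i in range(len(genotypes))]
    return GenotypeTable(ids, [locus], arr)


@pytest.fixture
def hha04_table() -> GenotypeTable:
    """The unique 22-bird configuration behind the panel's least diverse
    locus: 21 homozygotes 158/158 plus one heterozygote 158/162
    (allele counts 43:1)."""
    return single_locus_table("Hha04", [(158, 158)] * 21 + [(158, 162)])


@pytest.fixture
def hha01_table() -> GenotypeTable:
    """22 birds at a biallelic locus with 16 homozygotes and 6 heterozygotes
    (allele counts 38:6)."""
    return single_locus_table("Hha01", [(158, 158)] * 16 + [(158, 160)] * 6)


def equifrequent_loci(n_loci: int, n_alleles: int) -> dict[str, LocusFrequencies]:
    """n_loci loci with n_alleles equally frequent alleles each."""
    return {
        f"L{j:02d}": LocusFrequencies(
            f"L{j:02d}",
            tuple(range(1, n_alleles + 1)),
            tuple([1.0 / n_alleles] * n_alleles),
            0,
        )
        for j in range(n_loci)
    }


def random_frequency_vectors(rng: np.random.Generator, n: int, k_range=(2, 6)) -> list[np.ndarray]:
    """n Dirichlet-distributed allele-frequency vectors with 2-6 alleles."""
    out = []
    for _ in range(n):
        k = int(rng.integers(k_range[0], k_range[1] + 1))
        out.append(rng.dirichlet(np.full(k, 0.8)))
    return out
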