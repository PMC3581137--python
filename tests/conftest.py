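import numpy as np
import pytest

from simpute import GenotypeMatrix, generate_pool, simulate_genotypes


def matrix_from_array(arr, positions=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix with generated IDs from a plain array."""
    arr = np.asarray(arr, dtype=np.int16)
    return GenotypeMatrix(
        sample_ids=[f"S{i}" for i in range(arr.shape[0])],
        locus_ids=[f"L{j}" for j in range(arr.shape[1])],
        genotypes=arr,
        positions=positions,
    )


@pytest.fixture
def perfect_ld_matrix() -> GenotypeMatrix:
    """100 samples drawn from two complementary haplotypes (complete LD)."""
    pool = generate_pool(n_loci=6, n_haplotypes=2, ld_strength=1.0, seed=11)
    return simulate_genotypes(pool, n_samples=100, seed=12)


@pytest.fixture
def random_triple_matrix():
    """Factory for random 3-locus genotype matrices (for triple contexts)."""

    def make(seed: int, n_samples: int = 50) -> GenotypeMatrix:
        rng = np.random.default_rng(seed)
        haps = np.array(
            [[(h >> 2) & 1, (h >> 1) & 1, h & 1] for h in range(8)], dtype=np.int8
        )
        freqs = rng.dirichlet(np.ones(8) * 0.6)
        picks = rng.choice(8, size=(2, n_samples), p=freqs)
        geno = haps[picks[0]] + haps[picks[1]]
        return matrix_from_array(geno)

    return make
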