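import numpy as np
import pytest

from crossmappability.genome import GenomeSequence
from crossmappability.simulate import (
    DuplicationSpec,
    GeneSpec,
    generate_genome,
    simulate_study,
)

BASES = "ACGT"


def random_genome(rng: np.random.Generator, lengths: dict) -> GenomeSequence:
    return GenomeSequence(
        {
            chrom: "".join(np.array(list(BASES))[rng.integers(0, 4, size=n)])
            for chrom, n in lengths.items()
        }
    )


@pytest.fixture(scope="session")
def dup_fixture():
    """Two genes on different chromosomes, exact 100 bp exonic copy."""
    specs = [
        GeneSpec("geneA", "chr1", 400, (300,), utr5_len=60, utr3_len=60),
        GeneSpec("geneB", "chr2", 700, (300,), utr5_len=60, utr3_len=60),
    ]
    dups = [DuplicationSpec("geneA", "geneB", segment_length=100)]
    genome, models, truth = generate_genome(
        2, 3000, specs, dups, seed=11, mismatch_budgets=(0, 1, 2, 3)
    )
    return genome, models, truth


@pytest.fixture(scope="session")
def clean_fixture():
    """Random genome with genes and no planted duplications."""
    specs = [
        GeneSpec("g1", "chr1", 200, (250,), utr5_len=50),
        GeneSpec("g2", "chr2", 500, (200, 150), intron_lengths=(90,), utr3_len=40),
    ]
    genome, models, truth = generate_genome(
        2, 2500, specs, [], seed=5, mismatch_budgets=(0, 2)
    )
    return genome, models, truth


@pytest.fixture(scope="session")
def contaminated_study():
    """Default study conditions: n=500, alpha=0.5, beta_cis=1."""
    return simulate_study(n_samples=500, seed=101)
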