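import numpy as np
import pytest

import endzone as ez
from endzone.genome import GeneModel, GenomeSequence


@pytest.fixture
def toy_genome():
    """Two tiny contigs with hand-readable sequence."""
    return GenomeSequence({
        "chr1": "AACCGGTTACGTACGTAACC",
        "chr2": "CCCCCCCCCCGGGGGGGGGG",
    })


@pytest.fixture
def toy_gene():
    # stop codon ends at position 4; UTR = positions 5..14 (offsets 1..10)
    return GeneModel(gene_id="t1", chrom="chr1", strand="+",
                     stop_codon_end=4, utr_window=(0, 10))


@pytest.fixture(scope="session")
def small_synth():
    """A 30-gene synthetic dataset reused by read-through tests."""
    genome, genes, truth = ez.make_genome(30, seed=424242)
    return genome, genes, truth


@pytest.fixture(scope="session")
def small_series(small_synth):
    """Utilization series for the default slow-mutant tilt at depth 1e5."""
    _, _, truth = small_synth
    wt = ez.build_catalog(
        ez.simulate_endpoint_counts(truth, "wt", 100_000, seed=1), ez.YEAST)
    mut = ez.build_catalog(
        ez.simulate_endpoint_counts(truth, "mutant", 100_000, seed=2),
        ez.YEAST)
    return ez.combine_genotypes(wt, mut, ez.YEAST)
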