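import pandas as pd
import pytest

from chromreprog import synthetic as syn
from chromreprog.core import GeneAnnotation, PeakSet


@pytest.fixture(scope="session")
def small_genome():
    return syn.make_genome(2, 10_000_000, 25_000, seed=11)


@pytest.fixture(scope="session")
def small_genes(small_genome):
    return syn.place_genes(small_genome, 400, seed=12)


@pytest.fixture(scope="session")
def marks_dataset(small_genome, small_genes):
    """Planted states + noise-free marks, shared across landscape tests."""
    states = syn.plant_promoter_states(small_genes, seed=13)
    enhancers = syn.plant_enhancers(small_genome, small_genes, seed=14)
    marks, truth = syn.simulate_marks(
        small_genome, small_genes, states, enhancers=enhancers,
        snr=10.0, noise_sd=0.0, seed=15)
    return {"states": states, "enhancers": enhancers, "marks": marks,
            "truth": truth}


def peakset(rows):
    """Shorthand: build a PeakSet from (chrom, start, end[, signal]) tuples."""
    rows = [r if len(r) == 4 else (*r, 1.0) for r in rows]
    return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "signal"]))


def genes_from(rows):
    """Shorthand: GeneAnnotation from (gene_id, chrom, strand, tss[, start, end])."""
    cols = ["gene_id", "chrom", "strand", "tss", "start", "end"][:len(rows[0])]
    return GeneAnnotation(pd.DataFrame(rows, columns=cols))
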