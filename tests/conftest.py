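import numpy as np
import pytest

from promstr import (
    GeneModel,
    SimConfig,
    build_repeat_table,
    detect_genome,
    simulate_genome,
)


@pytest.fixture(scope="session")
def sim():
    """Default synthetic genome: 100 genes, 2 chromosomes, seed 1."""
    return simulate_genome(SimConfig(seed=1))


@pytest.fixture(scope="session")
def detected(sim):
    """Detector output on the default synthetic genome."""
    return detect_genome(sim.sequences)


@pytest.fixture(scope="session")
def truth_table(sim):
    """Repeat table built from the planted truth records."""
    table, counts = build_repeat_table(sim.truth_records(), sim.regions)
    return table, counts


@pytest.fixture(scope="session")
def sim_dir(sim, tmp_path_factory):
    """Default synthetic genome written to disk (FASTA, genes, BED, truth)."""
    outdir = tmp_path_factory.mktemp("simdata")
    return sim.write(str(outdir))


def make_gene(
    transcript="NM_000001",
    symbol=None,
    chrom="chr1",
    strand="+",
    tx=(10_000, 20_000),
    cds=None,
    exons=None,
):
    """Compact GeneModel builder for hand-written fixtures."""
    tx_start, tx_end = tx
    if exons is None:
        exons = [(tx_start, tx_end)]
    if cds is None:
        cds = (tx_start + 100, tx_end - 100)
    return GeneModel(
        transcriptId=transcript,
        geneSymbol=symbol or transcript,
        chrom=chrom,
        strand=strand,
        txStart=tx_start,
        txEnd=tx_end,
        cdsStart=cds[0],
        cdsEnd=cds[1],
        exonStarts=tuple(s for s, _ in exons),
        exonEnds=tuple(e for _, e in exons),
    )


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.4) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))
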