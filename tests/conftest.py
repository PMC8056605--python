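import numpy as np
import pytest
from hypothesis import settings

from grnexpress.intervals import ChipPeak, GeneModel, GenomicInterval, TranscriptModel
from grnexpress.simulate import (
    SimConfig,
    simulate_annotation,
    simulate_genotypes,
    simulate_regulation,
)

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")


def make_gene(
    gene_id="G1",
    chrom="chr1",
    strand="+",
    body=(100_000, 110_000),
    tx_specs=None,
):
    """Small gene factory.  tx_specs: list of (tx_id, start, end, [exon bounds])."""
    if tx_specs is None:
        tx_specs = [("T1", body[0], body[1], None)]
    transcripts = []
    for tx_id, start, end, exon_bounds in tx_specs:
        span = GenomicInterval(chrom, start, end, strand)
        if exon_bounds is None:
            exons = (span,)
        else:
            exons = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_bounds)
        transcripts.append(TranscriptModel(tx_id=tx_id, span=span, exons=exons))
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, transcripts=tuple(transcripts))


def make_peak(tf, start, end, chrom="chr1", signal=1.0):
    return ChipPeak(tf=tf, interval=GenomicInterval(chrom, start, end), signal=signal)


@pytest.fixture(scope="session")
def small_sim():
    """One small synthetic study shared across tests (fixed seed)."""
    cfg = SimConfig(seed=11, n_genes=30, n_tfs=8, n_samples=30, n_individuals=120)
    ann = simulate_annotation(cfg)
    reg = simulate_regulation(cfg, ann)
    gen = simulate_genotypes(cfg, ann, reg)
    return cfg, ann, reg, gen


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
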