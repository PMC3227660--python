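"""Shared fixtures: hand-built toy transcripts and seeded synthetic data."""

from __future__ import annotations

import pytest

from isocompare.model import GenomicInterval, TranscriptModel
from isocompare.simulate import (
    generate_gene_catalog,
    generate_paired_transcriptomes,
)


def make_transcript(
    exons,
    transcript_id="t1",
    gene_id="g1",
    chrom="chr1",
    strand="+",
):
    ivs = tuple(GenomicInterval(chrom, s, e) for s, e in exons)
    return TranscriptModel(transcript_id, gene_id, chrom, strand, ivs)


@pytest.fixture
def three_exon_gene():
    """Annotated gene with exons (0,100), (200,300), (400,500)."""
    return [make_transcript([(0, 100), (200, 300), (400, 500)], "ann1")]


@pytest.fixture(scope="session")
def small_catalog():
    catalog, genome = generate_gene_catalog(60, seed=11)
    return catalog, genome


@pytest.fixture(scope="session")
def planted_pair(small_catalog):
    catalog, _genome = small_catalog
    A, B, truth = generate_paired_transcriptomes(
        catalog,
        n_bifunctional=(3, 2, 1),
        switch_counts=(3, 2, 2, 1),
        n_splice_variants=(2, 2, 2),
        seed=11,
    )
    return catalog, A, B, truth
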