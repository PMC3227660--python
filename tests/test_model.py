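"""Domain types, annotation readers and canonical isoform identity."""

from __future__ import annotations

import itertools

import pytest

from isocompare.io import (
    AnnotationParseError,
    read_annotation,
    read_bed12,
    read_gtf,
    write_bed12,
    write_gtf,
)
from isocompare.model import (
    GenomicInterval,
    TranscriptModel,
    chains_match,
    exon_chain_key,
    extract_transcript_sequence,
)

from conftest import make_transcript


class TestInvariants:
    def test_interval_rejects_empty_and_negative(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 4)

    def test_transcript_rejects_unsorted_overlapping_adjacent_exons(self):
        for exons in ([(100, 200), (0, 50)], [(0, 100), (50, 150)], [(0, 100), (100, 200)]):
            with pytest.raises(ValueError):
                make_transcript(exons)

    def test_transcript_rejects_bad_strand_and_zero_exons(self):
        with pytest.raises(ValueError):
            make_transcript([(0, 10)], strand=".")
        with pytest.raises(ValueError):
            TranscriptModel("t", "g", "chr1", "+", ())

    def test_spliced_length_and_introns(self):
        t = make_transcript([(0, 100), (200, 300), (400, 500)])
        assert t.spliced_length == 300
        assert [(iv.start, iv.end) for iv in t.introns] == [(100, 200), (300, 400)]
        assert t.internal_boundaries() == (100, 200, 300, 400)


class TestAnnotationIO:
    def test_gtf_coordinates_convert_to_half_open(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1";\n'
        )
        catalog = read_gtf(gtf)
        (t,) = list(catalog)
        assert (t.exons[0].start, t.exons[0].end) == (100, 200)
        assert len(t.exons[0]) == 100

    def test_bed12_block_expansion(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text(
            "chr1\t0\t150\tG1|T1\t0\t+\t0\t150\t0\t2\t50,50\t0,100\n"
        )
        catalog = read_bed12(bed)
        t = catalog.transcript("T1")
        assert [(e.start, e.end) for e in t.exons] == [(0, 50), (100, 150)]
        assert t.gene_id == "G1"

    def test_transcripts_grouped_by_gene(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chr1\ts\texon\t1\t100\t.\t+\t.\tgene_id "G1"; transcript_id "T1";\n'
            'chr1\ts\texon\t201\t300\t.\t+\t.\tgene_id "G1"; transcript_id "T2";\n'
        )
        catalog = read_gtf(gtf)
        assert catalog.n_genes == 1
        assert {t.transcript_id for t in catalog.transcripts_of("G1")} == {"T1", "T2"}

    @pytest.mark.parametrize(
        "line,msg",
        [
            ("chr1\tonly\tthree", "9 tab-separated"),
            ('chr1\ts\texon\t1\t100\t.\t.\t.\tgene_id "G"; transcript_id "T";', "unstranded"),
            ('chr1\ts\texon\tx\t100\t.\t+\t.\tgene_id "G"; transcript_id "T";', "non-integer"),
            ('chr1\ts\texon\t1\t100\t.\t+\t.\tfoo "bar";', "missing gene_id"),
        ],
    )
    def test_gtf_errors_name_line_number(self, tmp_path, line, msg):
        gtf = tmp_path / "bad.gtf"
        gtf.write_text("# header\n" + line + "\n")
        with pytest.raises(AnnotationParseError) as err:
            read_gtf(gtf)
        assert err.value.lineno == 2
        assert msg in str(err.value)

    def test_bed12_zero_blocks_rejected(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("chr1\t0\t100\tT1\t0\t+\t0\t100\t0\t0\t\t\n")
        with pytest.raises(AnnotationParseError):
            read_bed12(bed)

    def test_round_trip_preserves_exon_coordinates(self, tmp_path, small_catalog):
        catalog, _ = small_catalog
        bed = tmp_path / "rt.bed"
        write_bed12(list(catalog), bed)
        back = read_bed12(bed)
        assert len(back) == len(catalog)
        for t in catalog:
            u = back.transcript(t.transcript_id)
            assert u.exons == t.exons and u.strand == t.strand
            assert u.gene_id == t.gene_id

    def test_gtf_round_trip(self, tmp_path, small_catalog):
        catalog, _ = small_catalog
        gtf = tmp_path / "rt.gtf"
        write_gtf(list(catalog), gtf)
        back = read_annotation(gtf, format="GTF")
        for t in catalog:
            assert back.transcript(t.transcript_id).exons == t.exons


class TestSequenceExtraction:
    GENOME = {"chr1": "AAACCCGGG"}

    def test_plus_strand_single_exon(self):
        t = make_transcript([(0, 3)])
        assert extract_transcript_sequence(self.GENOME, t) == "AAA"

    def test_minus_strand_reverse_complement(self):
        t = make_transcript([(0, 3)], strand="-")
        assert extract_transcript_sequence(self.GENOME, t) == "TTT"

    def test_splice_concatenation(self):
        t = make_transcript([(0, 3), (6, 9)])
        assert extract_transcript_sequence(self.GENOME, t) == "AAAGGG"

    def test_minus_strand_splice(self):
        # splice then reverse-complement as a whole
        t = make_transcript([(0, 3), (6, 9)], strand="-")
        assert extract_transcript_sequence(self.GENOME, t) == "CCCTTT"

    def test_bounds_and_lookup_errors(self):
        with pytest.raises(ValueError):
            extract_transcript_sequence(self.GENOME, make_transcript([(0, 50)]))
        with pytest.raises(KeyError):
            extract_transcript_sequence(self.GENOME, make_transcript([(0, 3)], chrom="chr2"))

    def test_length_matches_spliced_length_on_synthetic_catalog(self, small_catalog):
        catalog, genome = small_catalog
        for t in catalog:
            assert len(extract_transcript_sequence(genome, t)) == t.spliced_length


def _enumerate_chains(positions, max_exons):
    """All exon chains with <= max_exons exons and boundaries on a grid."""
    intervals = [
        (a, b) for a, b in itertools.combinations(positions, 2)
    ]
    chains = []
    for k in range(1, max_exons + 1):
        for combo in itertools.combinations(intervals, k):
            ok = all(
                combo[i][1] < combo[i + 1][0] for i in range(k - 1)
            )
            if ok:
                chains.append(combo)
    return chains


class TestExonChainKey:
    def test_identity_ignores_transcript_id(self):
        a = make_transcript([(0, 10), (20, 30)], "x")
        b = make_transcript([(0, 10), (20, 30)], "y")
        assert exon_chain_key(a) == exon_chain_key(b)

    def test_single_base_splice_shift_changes_key(self):
        a = make_transcript([(0, 10), (20, 30)])
        b = make_transcript([(0, 11), (20, 30)])
        assert exon_chain_key(a) != exon_chain_key(b)

    def test_strand_sensitivity(self):
        a = make_transcript([(0, 10)], strand="+")
        b = make_transcript([(0, 10)], strand="-")
        assert exon_chain_key(a) != exon_chain_key(b)

    def test_injective_over_all_small_chains_on_toy_chromosome(self):
        # every exon chain with <=3 exons on a 30-base toy chromosome
        # (boundaries on a 3-base grid) maps to a distinct key
        chains = _enumerate_chains(range(0, 31, 3), 3)
        keys = {}
        for i, chain in enumerate(chains):
            t = make_transcript(list(chain), f"t{i}")
            key = exon_chain_key(t)
            assert key not in keys, f"collision between {chain} and {keys[key]}"
            keys[key] = chain
        assert len(keys) == len(chains) > 500

    def test_terminal_tolerance_matching(self):
        a = make_transcript([(0, 100), (200, 300)])
        b = make_transcript([(5, 100), (200, 295)])
        assert not chains_match(a, b)
        assert chains_match(a, b, terminal_tolerance=5)
        c = make_transcript([(0, 100), (205, 300)])  # internal boundary moved
        assert not chains_match(a, c, terminal_tolerance=10)
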