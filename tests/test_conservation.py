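"""Conservation ratios against a brute-force per-base oracle."""

from __future__ import annotations

import numpy as np
import pytest

from isocompare.conservation import (
    ConservationTrack,
    base_conserved_fraction,
    clade_conservation_summary,
    element_overlap_ratio,
    merge_intervals,
)
from isocompare.model import GenomicInterval
from isocompare.simulate import generate_conservation_tracks, generate_gene_catalog

from conftest import make_transcript


def _brute_base_fraction(t, track, cutoff):
    scores = {}
    for s, e, score in track.score_runs.get(t.chrom, []):
        for p in range(s, e):
            scores[p] = score
    hits = total = 0
    for ex in t.exons:
        for p in range(ex.start, ex.end):
            total += 1
            if scores.get(p, 0.0) >= cutoff:
                hits += 1
    return hits / total


def _brute_element_ratio(t, merged):
    covered = set()
    for s, e in merged.get(t.chrom, []):
        covered.update(range(s, e))
    hit = sum(
        1 for ex in t.exons for p in range(ex.start, ex.end) if p in covered
    )
    return hit / t.spliced_length


class TestBaseConservedFraction:
    def test_fully_conserved_transcript(self):
        t = make_transcript([(0, 100), (200, 300)])
        track = ConservationTrack("vertebrates46", {"chr1": [(0, 300, 1.0)]})
        assert base_conserved_fraction(t, track) == 1.0

    def test_empty_track_gives_zero(self):
        t = make_transcript([(0, 100)])
        track = ConservationTrack("vertebrates46", {})
        assert base_conserved_fraction(t, track) == 0.0

    def test_half_conserved_exon(self):
        t = make_transcript([(0, 100)])
        track = ConservationTrack(
            "vertebrates46", {"chr1": [(0, 50, 1.0), (50, 100, 0.5)]}
        )
        assert base_conserved_fraction(t, track) == 0.5

    def test_matches_brute_force_on_random_tracks(self):
        rng = np.random.default_rng(5)
        for _ in range(15):
            t = make_transcript([(0, 40), (60, 100), (130, 160)])
            runs = []
            pos = 0
            while pos < 160:
                length = int(rng.integers(3, 20))
                runs.append((pos, min(pos + length, 160), float(rng.random())))
                pos += length + int(rng.integers(0, 10))
            track = ConservationTrack("primates10", {"chr1": runs})
            for cutoff in (0.3, 0.9):
                assert base_conserved_fraction(t, track, cutoff) == pytest.approx(
                    _brute_base_fraction(t, track, cutoff)
                )

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(9)
        t = make_transcript([(0, 100)])
        runs = [(i, i + 10, float(rng.random())) for i in range(0, 100, 10)]
        track = ConservationTrack("placental33", {"chr1": runs})
        fracs = [base_conserved_fraction(t, track, c) for c in (0.1, 0.5, 0.9)]
        assert fracs[0] >= fracs[1] >= fracs[2]

    def test_missing_bases_excluded_mode(self):
        t = make_transcript([(0, 100)])
        # only half the exon is scored, all above cutoff
        track = ConservationTrack("vertebrates46", {"chr1": [(0, 50, 0.95)]})
        assert base_conserved_fraction(t, track) == 0.5
        assert base_conserved_fraction(t, track, missing_as_zero=False) == 1.0


class TestElementOverlapRatio:
    def test_no_elements(self):
        t = make_transcript([(0, 100)])
        assert element_overlap_ratio(t, {}) == 0.0

    def test_full_coverage(self):
        t = make_transcript([(0, 100), (200, 300)])
        merged = merge_intervals([GenomicInterval("chr1", 0, 500)])
        assert element_overlap_ratio(t, merged) == 1.0

    def test_partial_exon_element(self):
        t = make_transcript([(0, 100)])
        merged = merge_intervals([GenomicInterval("chr1", 40, 60)])
        assert element_overlap_ratio(t, merged) == pytest.approx(0.2)

    def test_intronic_elements_never_contribute(self):
        t = make_transcript([(0, 100), (200, 300)])
        merged = merge_intervals([GenomicInterval("chr1", 120, 180)])
        assert element_overlap_ratio(t, merged) == 0.0

    def test_interval_arithmetic_matches_brute_force(self):
        rng = np.random.default_rng(13)
        t = make_transcript([(0, 50), (80, 140), (200, 260)])
        for _ in range(15):
            els = [
                GenomicInterval("chr1", int(s), int(s) + int(rng.integers(1, 40)))
                for s in rng.integers(0, 250, size=rng.integers(1, 8))
            ]
            merged = merge_intervals(els)
            assert element_overlap_ratio(t, merged) == pytest.approx(
                _brute_element_ratio(t, merged)
            )


class TestTrackReaders:
    def test_bedgraph_and_wiggle_agree_on_equivalent_content(self, tmp_path):
        from isocompare.io import read_bedgraph, read_score_track, read_wiggle

        bg = tmp_path / "t.bedgraph"
        bg.write_text("chr1\t0\t5\t0.9\nchr1\t10\t12\t0.5\n")
        wig = tmp_path / "t.wig"
        # fixedStep start=1 span=5 covers [0,5); variableStep 11 span=2 covers [10,12)
        wig.write_text(
            "fixedStep chrom=chr1 start=1 step=5 span=5\n0.9\n"
            "variableStep chrom=chr1 span=2\n11 0.5\n"
        )
        assert read_bedgraph(bg) == read_wiggle(wig)
        assert read_score_track(bg) == read_score_track(wig)

    def test_malformed_bedgraph_names_line(self, tmp_path):
        from isocompare.io import AnnotationParseError, read_bedgraph

        bad = tmp_path / "bad.bedgraph"
        bad.write_text("chr1\t0\t5\t0.9\nchr1\tnope\n")
        import pytest as _pytest

        with _pytest.raises(AnnotationParseError) as err:
            read_bedgraph(bad)
        assert err.value.lineno == 2


class TestCladeSummary:
    def test_planted_coverage_recovered_exactly(self):
        catalog, _ = generate_gene_catalog(40, isoforms_per_gene=1, seed=4)
        ts = list(catalog)
        tracks, truth = generate_conservation_tracks(ts, coverage_frac=0.8, seed=4)
        rows, aggregate = clade_conservation_summary(ts, tracks)
        assert aggregate == truth.clade_coverage
        assert all(v == 0.8 for v in aggregate.values())
        covered = {
            clade: {r.transcript_id for r in rows if r.clade == clade and r.contains_element}
            for clade in aggregate
        }
        assert covered == truth.covered_transcripts

    def test_zero_coverage_gives_all_zero_ratios(self):
        catalog, _ = generate_gene_catalog(10, isoforms_per_gene=1, seed=4)
        ts = list(catalog)
        tracks, _ = generate_conservation_tracks(ts, coverage_frac=0.0, seed=4)
        rows, aggregate = clade_conservation_summary(ts, tracks)
        assert all(v == 0.0 for v in aggregate.values())
        assert all(r.element_overlap_ratio == 0.0 for r in rows)

    def test_planted_element_fraction_realized(self):
        catalog, _ = generate_gene_catalog(20, isoforms_per_gene=1, seed=6)
        ts = list(catalog)
        tracks, truth = generate_conservation_tracks(
            ts, coverage_frac=1.0, element_fraction=0.2, seed=6
        )
        rows, _ = clade_conservation_summary(ts, tracks)
        for r in rows:
            planted = truth.element_fraction[(r.transcript_id, r.clade)]
            assert r.element_overlap_ratio == pytest.approx(planted)

    def test_contains_element_iff_positive_ratio(self):
        catalog, _ = generate_gene_catalog(15, seed=8)
        ts = list(catalog)
        tracks, _ = generate_conservation_tracks(ts, coverage_frac=0.5, seed=8)
        rows, _ = clade_conservation_summary(ts, tracks)
        for r in rows:
            assert r.contains_element == (r.element_overlap_ratio > 0)

    def test_transcript_on_missing_chromosome_flagged_with_zero(self):
        t = make_transcript([(0, 100)], chrom="chrZ")
        track = ConservationTrack("vertebrates46", {"chr1": [(0, 100, 1.0)]})
        rows, aggregate = clade_conservation_summary([t], [track])
        assert rows[0].missing_chrom and rows[0].base_conserved_fraction == 0.0
        assert aggregate["vertebrates46"] == 0.0

    def test_base_scores_select_exactly_planted_bases(self):
        catalog, _ = generate_gene_catalog(10, isoforms_per_gene=1, seed=3)
        ts = list(catalog)
        tracks, truth = generate_conservation_tracks(ts, coverage_frac=1.0, seed=3)
        for track in tracks:
            for t in ts:
                frac = base_conserved_fraction(t, track, 0.9)
                assert frac == pytest.approx(
                    truth.element_fraction[(t.transcript_id, track.clade)]
                )
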