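"""Two-sample overlap operations against brute-force oracles and planted truth."""

from __future__ import annotations

import numpy as np
import pytest

from isocompare.coding import classify_sample
from isocompare.compare import (
    bifunctional_union,
    category_switch_genes,
    compare_gene_sets,
    compare_isoform_sets,
    distribution_tables,
    exon_count_bins,
    identical_isoform_set_genes,
    mean_isoforms_per_gene,
    multi_exon_share,
    one_isoform_share,
    round_pct,
    set_overlap,
)
from isocompare.model import ExpressionRecord, SampleTranscriptome, exon_chain_key

from conftest import make_transcript


def _sample(name, transcripts):
    s = SampleTranscriptome(name)
    for t in transcripts:
        s.add(t, ExpressionRecord(t.transcript_id, 1.0))
    return s


def _random_sample(name, rng, n_genes=8, tag=""):
    ts = []
    for g in range(n_genes):
        gid = f"g{g}"
        for i in range(rng.integers(1, 4)):
            start = g * 1000 + i * 120
            exons = [(start, start + 50)]
            if rng.random() < 0.5:
                exons.append((start + 60, start + 100))
            ts.append(make_transcript(exons, f"{tag}{gid}.t{i}", gid))
    keep = [t for t in ts if rng.random() < 0.8]
    return _sample(name, keep or ts[:1])


class TestGeneOverlap:
    def test_identical_samples_have_no_exclusive_genes(self):
        t = make_transcript([(0, 100)])
        A = _sample("a", [t])
        B = _sample("b", [t])
        out = compare_gene_sets(A, B)
        assert out.a_only == out.b_only == frozenset()
        assert out.pct_a_only == out.pct_b_only == 0.0

    def test_matches_exhaustive_enumeration_on_random_toys(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a_ids = {f"g{i}" for i in rng.choice(20, size=rng.integers(1, 15), replace=False)}
            b_ids = {f"g{i}" for i in rng.choice(20, size=rng.integers(1, 15), replace=False)}
            out = set_overlap(a_ids, b_ids)
            # brute force: test membership of every id of the universe
            common = {g for g in a_ids if g in b_ids}
            assert set(out.common) == common
            assert set(out.a_only) == {g for g in a_ids if g not in b_ids}
            assert set(out.b_only) == {g for g in b_ids if g not in a_ids}
            assert len(out.common) + len(out.a_only) == len(a_ids)
            assert len(out.common) + len(out.b_only) == len(b_ids)

    def test_symmetry_under_sample_swap(self):
        rng = np.random.default_rng(3)
        A = _random_sample("a", rng)
        B = _random_sample("b", rng)
        ab = compare_gene_sets(A, B)
        ba = compare_gene_sets(B, A)
        assert ab.common == ba.common
        assert ab.a_only == ba.b_only and ab.b_only == ba.a_only


class TestIsoformOverlap:
    def test_disjoint_sets_are_fully_exclusive(self):
        A = _sample("a", [make_transcript([(0, 100)], "x", "g1")])
        B = _sample("b", [make_transcript([(200, 300)], "y", "g1")])
        out = compare_isoform_sets(A, B)
        assert out.common == frozenset()
        assert out.pct_a_only == 100.0

    def test_identity_modes_agree_when_ids_track_structures(self):
        ts = [
            make_transcript([(0, 100)], "t1", "g1"),
            make_transcript([(0, 100), (200, 300)], "t2", "g1"),
            make_transcript([(500, 700)], "t3", "g2"),
        ]
        A = _sample("a", ts)
        B = _sample("b", ts[:2])
        by_chain = compare_isoform_sets(A, B, "exon_chain")
        by_id = compare_isoform_sets(A, B, "transcript_id")
        assert len(by_chain.common) == len(by_id.common) == 2
        assert len(by_chain.a_only) == len(by_id.a_only) == 1

    def test_oracle_equivalence_on_small_catalogs(self, planted_pair):
        _catalog, A, B, _truth = planted_pair
        out = compare_isoform_sets(A, B)
        # exhaustive pairwise comparison oracle
        keys_a = {exon_chain_key(t) for t in A.transcripts()}
        keys_b = {exon_chain_key(t) for t in B.transcripts()}
        common = set()
        for t in A.transcripts():
            for u in B.transcripts():
                if (
                    t.chrom == u.chrom
                    and t.strand == u.strand
                    and t.exons == u.exons
                ):
                    common.add(exon_chain_key(t))
        assert set(out.common) == common
        assert set(out.a_only) == keys_a - keys_b
        assert len(out.common) + len(out.a_only) == len(A)
        assert len(out.common) + len(out.b_only) == len(B)

    def test_cross_gene_key_collision_reported_and_excluded(self):
        # same exon chain claimed by two different genes
        t1 = make_transcript([(0, 100)], "t1", "g1")
        t2 = make_transcript([(0, 100)], "t2", "g2")
        A = _sample("a", [t1])
        B = _sample("b", [t2])
        out = compare_isoform_sets(A, B)
        assert len(out.ambiguous_keys) == 1

    def test_coding_subcounts_sum_to_partition_sizes(self, planted_pair):
        _catalog, A, B, truth = planted_pair
        ass_a, _ = classify_sample(A, truth.coding_scores)
        ass_b, _ = classify_sample(B, truth.coding_scores)
        out = compare_isoform_sets(A, B, "exon_chain", ass_a, ass_b)
        for part, keys in (
            ("common", out.common),
            ("a_only", out.a_only),
            ("b_only", out.b_only),
        ):
            assert out.coding_counts[part] + out.noncoding_counts[part] == len(keys)


class TestIdenticalSetAndSwitches:
    def test_equal_and_unequal_isoform_sets(self):
        t1 = make_transcript([(0, 100)], "t1", "g1")
        t2 = make_transcript([(0, 100), (200, 300)], "t2", "g1")
        A = _sample("a", [t1, t2])
        B_eq = _sample("b", [t1, t2])
        B_sub = _sample("b", [t1])
        assert identical_isoform_set_genes(A, B_eq) == {"g1"}
        assert identical_isoform_set_genes(A, B_sub) == set()

    def test_planted_identical_fraction_recovered_exactly(self, planted_pair):
        _catalog, A, B, truth = planted_pair
        assert identical_isoform_set_genes(A, B) == truth.identical_set_genes

    def test_planted_switch_counts_recovered_exactly(self, planted_pair):
        _catalog, A, B, truth = planted_pair
        ass_a, _ = classify_sample(A, truth.coding_scores)
        ass_b, _ = classify_sample(B, truth.coding_scores)
        sw = category_switch_genes(A, B, ass_a, ass_b)
        assert set(sw.lncrna_a_only) == truth.switch_lnc_a_only
        assert set(sw.lncrna_b_only) == truth.switch_lnc_b_only
        assert set(sw.coding_a_only) == truth.switch_cod_a_only
        assert set(sw.coding_b_only) == truth.switch_cod_b_only


class TestBifunctionalUnion:
    def test_disjoint_sets_add(self, planted_pair):
        _catalog, A, B, truth = planted_pair
        _, cat_a = classify_sample(A, truth.coding_scores)
        _, cat_b = classify_sample(B, truth.coding_scores)
        union, common = bifunctional_union(cat_a, cat_b)
        assert union == truth.bifunctional_a | truth.bifunctional_b
        assert common == truth.bifunctional_a & truth.bifunctional_b


class TestDistributions:
    def test_all_single_exon_gives_zero_multi_share(self):
        ts = [make_transcript([(i * 200, i * 200 + 100)], f"t{i}", f"g{i}") for i in range(4)]
        sample = _sample("s", ts)
        bins = exon_count_bins(sample)
        assert bins == {"1": 4, "2": 0, "3": 0, "4": 0, "5": 0, "6+": 0}
        assert multi_exon_share(bins) == 0.0

    def test_histograms_sum_to_totals(self, planted_pair):
        _catalog, A, _B, _truth = planted_pair
        tables = distribution_tables(A)
        assert sum(tables["exon_bins"].values()) == len(A)
        assert sum(tables["isoform_bins"].values()) == len(A.gene_ids())

    def test_one_isoform_gene_mean(self):
        ts = [make_transcript([(i * 200, i * 200 + 100)], f"t{i}", f"g{i}") for i in range(3)]
        sample = _sample("s", ts)
        assert one_isoform_share(distribution_tables(sample)["isoform_bins"]) == 100.0
        assert mean_isoforms_per_gene(len(sample), len(sample.gene_ids())) == 1.00

    def test_mean_requires_genes(self):
        with pytest.raises(ValueError):
            mean_isoforms_per_gene(5, 0)


class TestRounding:
    def test_half_up_to_two_decimals(self):
        assert round_pct(5164, 16818) == 30.71
        assert round_pct(1, 8) == 12.5
        assert round_pct(1, 3) == 33.33
        # exact .005 boundary rounds up
        assert round_pct(1005, 100000) == 1.01
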