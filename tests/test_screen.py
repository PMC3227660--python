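"""Probe matching, differential expression and the correlation screen."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from isocompare.model import extract_transcript_sequence
from isocompare.screen import (
    Probe,
    correlation_screen,
    differential_expression,
    match_probes,
)
from isocompare.simulate import generate_disease_matrices, generate_gene_catalog

from conftest import make_transcript


def _targets():
    t1 = make_transcript([(0, 30)], "t1", "g1")
    t2 = make_transcript([(100, 130)], "t2", "g2")
    return [
        (t1, "ACGTACGTACGTAAACCCGGGTTTACGTAC"),
        (t2, "TTTTTTTTTTAAACCCGGGTTTTTTTTTTT"),
    ]


class TestMatchProbes:
    def test_unique_match_reported_with_offset(self):
        probes = [Probe("p1", "ACGTACGTACGT")]
        matches, rejected = match_probes(probes, _targets())
        assert len(matches) == 1
        m = matches[0]
        assert (m.transcript_id, m.offset, m.unique) == ("t1", 0, True)
        assert rejected == {}

    def test_probe_in_two_transcripts_excluded(self):
        probes = [Probe("p1", "AAACCCGGG")]
        matches, rejected = match_probes(probes, _targets())
        assert matches == []
        assert "non-unique" in rejected["p1"]

    def test_repeated_occurrence_within_one_transcript_excluded(self):
        probes = [Probe("p1", "TTTTTTTTTT")]
        matches, rejected = match_probes(probes, _targets())
        assert matches == [] and "non-unique" in rejected["p1"]

    def test_absent_probe_excluded(self):
        probes = [Probe("p1", "GGGGGGGGGGGG")]
        matches, rejected = match_probes(probes, _targets())
        assert matches == [] and rejected["p1"] == "no match"

    def test_gene_symbol_prefilter(self):
        probes = [Probe("p1", "ACGTACGTACGT", gene_symbol="TP53")]
        matches, rejected = match_probes(
            probes, _targets(), require_gene_symbol_absent=True
        )
        assert matches == [] and rejected["p1"] == "has gene symbol"

    def test_both_orientations_flag(self):
        # reverse complement of ACGTACGTACGT is itself-shifted; use asymmetric
        probes = [Probe("p1", "CCCGGGTTTATG")]  # rc = CATAAACCCGGG not present
        rc_present = [Probe("p2", "GTACGTACGTTT")]  # rc = AAACGTACGTAC
        seqs = [(_targets()[0][0], "AAACGTACGTAC")]
        m1, _ = match_probes(rc_present, seqs)
        assert m1 == []
        m2, _ = match_probes(rc_present, seqs, both_orientations=True)
        assert len(m2) == 1

    def test_equals_naive_scan_on_synthetic_sequences(self, small_catalog):
        catalog, genome = small_catalog
        with_seqs = [
            (t, extract_transcript_sequence(genome, t)) for t in catalog
        ][:40]
        rng = np.random.default_rng(21)
        probes = []
        for i in range(25):
            t, seq = with_seqs[int(rng.integers(0, len(with_seqs)))]
            off = int(rng.integers(0, max(len(seq) - 20, 1)))
            probes.append(Probe(f"p{i}", seq[off : off + 20]))
        probes.append(Probe("random", "ACGT" * 5))
        matches, rejected = match_probes(probes, with_seqs)
        # naive oracle over every (probe, transcript, offset) triple
        for p in probes:
            occ = [
                (t.transcript_id, off)
                for t, seq in with_seqs
                for off in range(len(seq) - len(p.sequence) + 1)
                if seq[off : off + len(p.sequence)] == p.sequence
            ]
            mine = [m for m in matches if m.probe_id == p.probe_id]
            if len(occ) == 1:
                assert len(mine) == 1
                assert (mine[0].transcript_id, mine[0].offset) == occ[0]
            else:
                assert mine == [] and p.probe_id in rejected


def _matrix(values, samples):
    return pd.DataFrame(values, columns=samples)


class TestDifferentialExpression:
    def test_constant_probe_never_differential(self):
        samples = [f"s{i}" for i in range(8)]
        mat = _matrix([[5.0] * 8, [1, 2, 3, 4, 50, 60, 70, 80]], samples)
        mat.index = ["const", "shift"]
        res = differential_expression(mat, samples[:4], samples[4:])
        by_id = {r.probe_id: r for r in res}
        assert by_id["const"].constant and by_id["const"].p_value == 1.0
        assert not by_id["const"].differential
        assert by_id["shift"].differential

    def test_small_groups_rejected(self):
        mat = _matrix([[1.0, 2.0, 3.0]], ["a", "b", "c"])
        with pytest.raises(ValueError):
            differential_expression(mat, ["a"], ["b", "c"])

    def test_q_values_monotone_in_p_value_rank(self):
        nc, _, cases, ctrls, _ = generate_disease_matrices(
            n_probes=150, de_frac=0.1, seed=17
        )
        res = differential_expression(nc, cases, ctrls)
        ordered = sorted(res, key=lambda r: r.p_value)
        qs = [r.q_value for r in ordered]
        assert all(q1 <= q2 + 1e-12 for q1, q2 in zip(qs, qs[1:]))
        assert all(r.q_value >= r.p_value - 1e-12 for r in res)

    def test_planted_shift_recovered_with_high_power(self):
        nc, _, cases, ctrls, truth = generate_disease_matrices(
            n_probes=100, de_frac=0.1, effect_size=4.0, n_case=10, n_control=10,
            seed=23,
        )
        res = differential_expression(nc, cases, ctrls)
        flagged = {r.probe_id for r in res if r.differential}
        assert len(flagged & truth.de_probes) >= 9


class TestCorrelationScreen:
    def test_perfectly_collinear_pair_is_a_hit(self):
        x = np.arange(10, dtype=float)
        nc = pd.DataFrame([x], index=["n1"], columns=[f"s{i}" for i in range(10)])
        g = pd.DataFrame([2 * x + 1], index=["g1"], columns=nc.columns)
        hits, skipped = correlation_screen(nc, g)
        assert len(hits) == 1 and hits[0].r == pytest.approx(1.0)
        assert hits[0].p_value == 0.0

    def test_r_threshold_is_inclusive_at_exact_boundary(self):
        # integer patterns with r = 8m / sqrt(20m * 20m) = 0.4 exactly
        m = 24
        x = np.tile([3.0, 1.0, -1.0, -3.0, 0.0], m)
        y = np.tile([-1.0, 3.0, 1.0, -3.0, 0.0], m)
        cols = [f"s{i}" for i in range(x.size)]
        nc = pd.DataFrame([x], index=["n1"], columns=cols)
        g = pd.DataFrame([y], index=["g1"], columns=cols)
        hits, _ = correlation_screen(nc, g, r_min=0.4)
        assert len(hits) == 1
        assert hits[0].r == 0.4
        assert hits[0].p_value < 0.05

    def test_negative_correlations_count_by_magnitude(self):
        x = np.arange(12, dtype=float)
        cols = [f"s{i}" for i in range(12)]
        nc = pd.DataFrame([x], index=["n1"], columns=cols)
        g = pd.DataFrame([-x], index=["g1"], columns=cols)
        hits, _ = correlation_screen(nc, g)
        assert len(hits) == 1 and hits[0].r == pytest.approx(-1.0)

    def test_zero_variance_vector_skipped(self):
        cols = [f"s{i}" for i in range(6)]
        nc = pd.DataFrame([[1.0] * 6], index=["n1"], columns=cols)
        g = pd.DataFrame([np.arange(6.0)], index=["g1"], columns=cols)
        hits, skipped = correlation_screen(nc, g)
        assert hits == [] and skipped == [("n1", "g1", "zero variance")]

    def test_invariant_under_joint_sample_permutation(self):
        rng = np.random.default_rng(31)
        cols = [f"s{i}" for i in range(20)]
        x = rng.normal(size=20)
        y = 0.7 * x + rng.normal(size=20) * 0.5
        nc = pd.DataFrame([x], index=["n1"], columns=cols)
        g = pd.DataFrame([y], index=["g1"], columns=cols)
        hits1, _ = correlation_screen(nc, g, r_min=0.0, p_max=1.0)
        perm = rng.permutation(20)
        cols_p = [cols[i] for i in perm]
        hits2, _ = correlation_screen(nc[cols_p], g[cols_p], r_min=0.0, p_max=1.0)
        assert hits1[0].r == pytest.approx(hits2[0].r)
        assert hits1[0].p_value == pytest.approx(hits2[0].p_value)

    def test_planted_high_rho_pairs_recovered(self):
        recovered = total = 0
        for seed in range(25):
            nc, g, *_ , truth = generate_disease_matrices(
                n_probes=40, corr_pairs=4, rho=0.9, n_case=20, n_control=20,
                de_frac=0.0, seed=seed,
            )
            hits, _ = correlation_screen(
                np.log2(nc + 1), np.log2(g + 1), pairs=truth.corr_pairs
            )
            found = {(h.ncrna_probe_id, h.gene_probe_id) for h in hits}
            recovered += len(found)
            total += len(truth.corr_pairs)
        assert recovered / total >= 0.95
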