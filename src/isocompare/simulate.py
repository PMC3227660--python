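"""Synthetic inputs with recorded ground truth for every pipeline stage.

The generators emulate the study conditions the pipeline was built for: a
multi-isoform gene catalog on a toy genome, a pair of sample transcriptomes
with controlled gene/isoform sharing, CPC-style coding scores with a planted
coding/noncoding split, conservation tracks with planted conserved elements
for three clades, and case/control expression matrices with planted
differentially expressed probes and planted probe-gene correlations.

Planting discipline: every quantity a downstream operation is supposed to
recover is fixed here by explicit construction and recorded in
:class:`GroundTruth`; realized values are bookkept from the constructed sets
themselves (never by running the pipeline), so recovery tests are exact.

Default shapes mirror annotation-based quantification of real tissue pairs:
genes carry a multi-isoform annotation (mean ~2.6 isoforms) of which mostly
one isoform is expressed per sample; most transcripts have two or more exons
with a heavy >=6-exon tail; gene-level sharing between the two samples (0.66)
far exceeds isoform-level sharing (0.35) — the qualitative reversal the
comparison exists to expose; and RPKM values are log-normal with a long tail
plus deliberate mass at and just below the 0.1 expressed threshold to
exercise the inclusive boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .coding import LNCRNA_MIN_LENGTH
from .conservation import CLADES, ConservationTrack
from .model import (
    ExpressionRecord,
    GeneCatalog,
    GenomicInterval,
    SampleTranscriptome,
    TranscriptModel,
    exon_chain_key,
)
from .splice import SpliceClass

__all__ = [
    "GroundTruth",
    "generate_gene_catalog",
    "generate_paired_transcriptomes",
    "generate_conservation_tracks",
    "generate_disease_matrices",
]

Distribution = Union[int, Sequence[float]]

# catalog geometry (bases)
_EXON_LEN_RANGE = (80, 300)
_INTRON_LEN_RANGE = (60, 200)
_GENE_GAP = 100

# annotated isoforms per gene (weights for 1..6)
DEFAULT_ISOFORMS_PER_GENE = (0.25, 0.30, 0.20, 0.12, 0.08, 0.05)
# exons per isoform (weights for 1..10; heavy multi-exon tail)
DEFAULT_EXONS_PER_ISOFORM = (0.06, 0.08, 0.10, 0.11, 0.10, 0.15, 0.14, 0.12, 0.08, 0.06)
# expressed isoforms per expressed gene (weights for 1..6; mostly one)
DEFAULT_EXPRESSED_PER_GENE = (0.66, 0.17, 0.08, 0.04, 0.02, 0.03)


@dataclass
class GroundTruth:
    """Everything the generators planted, for exact recovery checks."""

    seed: int
    # paired transcriptomes
    genes_common: Set[str] = field(default_factory=set)
    genes_a_only: Set[str] = field(default_factory=set)
    genes_b_only: Set[str] = field(default_factory=set)
    isoforms_common: int = 0
    isoforms_a_total: int = 0
    isoforms_b_total: int = 0
    shared_gene_frac: float = 0.0
    shared_isoform_frac: float = 0.0
    identical_set_genes: Set[str] = field(default_factory=set)
    coding_label: Dict[str, bool] = field(default_factory=dict)  # tid -> is coding
    coding_scores: Dict[str, float] = field(default_factory=dict)
    bifunctional_a: Set[str] = field(default_factory=set)
    bifunctional_b: Set[str] = field(default_factory=set)
    switch_lnc_a_only: Set[str] = field(default_factory=set)
    switch_lnc_b_only: Set[str] = field(default_factory=set)
    switch_cod_a_only: Set[str] = field(default_factory=set)
    switch_cod_b_only: Set[str] = field(default_factory=set)
    splice_class: Dict[str, SpliceClass] = field(default_factory=dict)
    # conservation
    covered_transcripts: Dict[str, Set[str]] = field(default_factory=dict)
    element_fraction: Dict[Tuple[str, str], float] = field(default_factory=dict)
    clade_coverage: Dict[str, float] = field(default_factory=dict)
    # disease screen
    de_probes: Set[str] = field(default_factory=set)
    effect_size: float = 0.0
    corr_pairs: List[Tuple[str, str]] = field(default_factory=list)
    rho: float = 0.0


def _draw(dist: Distribution, rng: np.random.Generator) -> int:
    if isinstance(dist, (int, np.integer)):
        if dist < 1:
            raise ValueError("distribution value must be >= 1")
        return int(dist)
    weights = np.asarray(dist, dtype=float)
    if weights.ndim != 1 or weights.size == 0 or (weights < 0).any():
        raise ValueError("weights must be a non-empty non-negative vector")
    weights = weights / weights.sum()
    return int(rng.choice(np.arange(1, weights.size + 1), p=weights))


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


# ---------------------------------------------------------------------------
# gene catalog
# ---------------------------------------------------------------------------


def generate_gene_catalog(
    n_genes: int,
    isoforms_per_gene: Distribution = DEFAULT_ISOFORMS_PER_GENE,
    exons_per_isoform: Distribution = DEFAULT_EXONS_PER_ISOFORM,
    seed: int = 0,
    chrom: str = "chr1",
    chrom_length: Optional[int] = None,
) -> Tuple[GeneCatalog, Dict[str, str]]:
    """Non-overlapping multi-isoform gene loci on a toy chromosome.

    Isoforms of a gene are distinct ordered subsets of a shared master exon
    chain, so siblings share exons the way annotated isoforms do.  Returns the
    catalog and a {chrom: sequence} genome.  Deterministic per seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    catalog = GeneCatalog()
    cursor = _GENE_GAP
    for gi in range(n_genes):
        gene_id = f"G{gi + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        k = _draw(isoforms_per_gene, rng)
        exon_draws = [_draw(exons_per_isoform, rng) for _ in range(k)]
        max_e = max(exon_draws)
        n_master = max_e + (2 if k > 1 else 0)
        # grow the master chain until enough distinct subsets exist
        while any(math.comb(n_master, e) < exon_draws.count(e) for e in set(exon_draws)):
            n_master += 1
        exon_lens = rng.integers(*_EXON_LEN_RANGE, size=n_master)
        intron_lens = rng.integers(*_INTRON_LEN_RANGE, size=max(n_master - 1, 1))
        master: List[Tuple[int, int]] = []
        pos = cursor
        for j in range(n_master):
            master.append((pos, pos + int(exon_lens[j])))
            pos += int(exon_lens[j])
            if j < n_master - 1:
                pos += int(intron_lens[j])
        cursor = pos + _GENE_GAP

        chosen: Set[Tuple[int, ...]] = set()
        for ti, e in enumerate(exon_draws, start=1):
            for _ in range(200):
                subset = tuple(sorted(rng.choice(n_master, size=e, replace=False)))
                if subset not in chosen:
                    chosen.add(subset)
                    break
            else:  # pragma: no cover - guarded by the comb() check above
                raise RuntimeError("could not draw a distinct isoform structure")
            exons = tuple(
                GenomicInterval(chrom, master[j][0], master[j][1]) for j in subset
            )
            catalog.add(
                TranscriptModel(f"{gene_id}.t{ti}", gene_id, chrom, strand, exons)
            )
    needed = cursor
    if chrom_length is not None:
        if chrom_length < needed:
            raise ValueError(
                f"cannot pack {n_genes} genes into {chrom_length} bases "
                f"(need {needed})"
            )
        needed = chrom_length
    genome = {chrom: _random_sequence(rng, needed)}
    return catalog, genome


# ---------------------------------------------------------------------------
# paired transcriptomes
# ---------------------------------------------------------------------------


def _short_filler(t: TranscriptModel, suffix: str) -> TranscriptModel:
    """A short (<=200 nt) single-exon transcript inside the gene's first exon.

    A neutral noncoding filler: never a long ncRNA and never protein-coding,
    so it cannot create bifunctional genes or category switches, yet it keeps
    a gene expressed (or makes two expressed sets differ).
    """
    ex = t.exons[0]
    length = min(len(ex), LNCRNA_MIN_LENGTH - 51)  # 150 nt for typical exons
    return TranscriptModel(
        f"{t.gene_id}.{suffix}",
        t.gene_id,
        t.chrom,
        t.strand,
        (GenomicInterval(ex.chrom, ex.start, ex.start + length),),
    )


def _splice_variant(
    t: TranscriptModel,
    annotated: Sequence[TranscriptModel],
    cls: SpliceClass,
    suffix: str,
) -> Optional[TranscriptModel]:
    """Edit an annotated chain to realize one splice class, or None if the
    edit is infeasible or ambiguous for this template."""
    keys = {exon_chain_key(a) for a in annotated}
    boundaries = {b for a in annotated for ex in a.exons for b in (ex.start, ex.end)}
    introns = {(iv.start, iv.end) for a in annotated for iv in a.introns}
    if cls == SpliceClass.INTRON_RETENTION:
        if t.num_exons < 2:
            return None
        ex1, ex2 = t.exons[0], t.exons[1]
        merged = (GenomicInterval(t.chrom, ex1.start, ex2.end),) + t.exons[2:]
        out = TranscriptModel(
            f"{t.transcript_id}.{suffix}", t.gene_id, t.chrom, t.strand, merged
        )
    elif cls == SpliceClass.NOVEL_BOUNDARY_OR_EXON:
        if t.num_exons < 2:
            return None
        ex1 = t.exons[0]
        shift = None
        for d in range(7, min(len(ex1), 40)):
            if ex1.end - d not in boundaries and ex1.end - d > ex1.start:
                shift = d
                break
        if shift is None:
            return None
        new_first = GenomicInterval(t.chrom, ex1.start, ex1.end - shift)
        out = TranscriptModel(
            f"{t.transcript_id}.{suffix}",
            t.gene_id,
            t.chrom,
            t.strand,
            (new_first,) + t.exons[1:],
        )
        # shrinking an exon cannot engulf an intron, and internal boundaries
        # other than the new one stay annotated
    elif cls == SpliceClass.EXON_SKIPPING:
        if t.num_exons < 3:
            return None
        out = TranscriptModel(
            f"{t.transcript_id}.{suffix}",
            t.gene_id,
            t.chrom,
            t.strand,
            t.exons[:1] + t.exons[2:],  # drop the second exon
        )
        # the skip must not leave an exon engulfing an annotated intron
        for ex in out.exons:
            if any(ex.start < s and e < ex.end for s, e in introns):
                return None
    else:  # pragma: no cover
        return None
    if exon_chain_key(out) in keys:
        return None
    return out


def generate_paired_transcriptomes(
    catalog: GeneCatalog,
    shared_gene_frac: float = 0.66,
    shared_isoform_frac: float = 0.35,
    coding_frac: float = 0.9,
    identical_set_frac: float = 0.3,
    expressed_per_gene: Distribution = DEFAULT_EXPRESSED_PER_GENE,
    n_bifunctional: Tuple[int, int, int] = (0, 0, 0),
    switch_counts: Tuple[int, int, int, int] = (0, 0, 0, 0),
    n_splice_variants: Tuple[int, int, int] = (0, 0, 0),
    seed: int = 0,
    sample_a: str = "brain",
    sample_b: str = "cell_lines",
) -> Tuple[SampleTranscriptome, SampleTranscriptome, GroundTruth]:
    """Two sample transcriptomes with controlled sharing and planted events.

    Parameters
    ----------
    shared_gene_frac
        Fraction of catalog genes expressed in both samples; the rest split
        between A-only and B-only.
    shared_isoform_frac
        Target fraction of sample A's expressed isoforms also expressed in B,
        realized by tuning per-gene expressed-subset overlap in the ordinary
        common genes.  Infeasible targets (below what the identical-set and
        single-isoform genes force, or above what the common genes allow)
        raise a constraint error.
    coding_frac
        Probability that an ordinary gene is protein-coding (all its isoforms
        score positive); noncoding genes score negative throughout.
    identical_set_frac
        Fraction of common genes whose expressed isoform sets are exactly
        equal in both samples; single-isoform genes are preferred hosts.
    expressed_per_gene
        Distribution of expressed isoforms per expressed gene (clipped to the
        gene's annotated isoform count).
    n_bifunctional
        (A-exclusive, B-exclusive, common) bifunctional gene counts.
        Exclusive bifunctional genes live among sample-exclusive genes so they
        cannot double as category-switch genes; common ones keep identical
        isoform sets and sit inside the identical-set quota.
    switch_counts
        (lncRNA in A only, lncRNA in B only, coding in A only, coding in B
        only) among common genes; the opposite sample gets a short noncoding
        filler isoform so the gene stays expressed without switching class.
    n_splice_variants
        Novel transcripts per class (intron retention, novel boundary/exon,
        exon skipping) added to sample A on noncoding A-exclusive host genes.
    """
    for name, frac in (
        ("shared_gene_frac", shared_gene_frac),
        ("shared_isoform_frac", shared_isoform_frac),
        ("coding_frac", coding_frac),
        ("identical_set_frac", identical_set_frac),
    ):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must be in [0,1]")
    rng = np.random.default_rng(seed)
    truth = GroundTruth(seed=seed)
    gene_ids = sorted(catalog.genes)
    n_genes = len(gene_ids)

    n_common = round(shared_gene_frac * n_genes)
    n_rest = n_genes - n_common
    order = list(rng.permutation(gene_ids))
    common = order[:n_common]
    a_only = order[n_common : n_common + (n_rest + 1) // 2]
    b_only = order[n_common + (n_rest + 1) // 2 :]

    bif_a_n, bif_b_n, bif_c_n = n_bifunctional
    sw_lnc_a, sw_lnc_b, sw_cod_a, sw_cod_b = switch_counts
    n_switch = sw_lnc_a + sw_lnc_b + sw_cod_a + sw_cod_b

    def pick(pool: List[str], n: int, need_multi: bool, what: str) -> List[str]:
        chosen: List[str] = []
        for gid in list(pool):
            if len(chosen) == n:
                break
            if need_multi and len(catalog.genes[gid]) < 2:
                continue
            chosen.append(gid)
            pool.remove(gid)
        if len(chosen) < n:
            raise ValueError(f"catalog too small to plant {n} {what} genes")
        return chosen

    a_pool, b_pool, c_pool = list(a_only), list(b_only), list(common)
    bif_a_genes = pick(a_pool, bif_a_n, need_multi=True, what="A-bifunctional")
    bif_b_genes = pick(b_pool, bif_b_n, need_multi=True, what="B-bifunctional")
    bif_c_genes = pick(c_pool, bif_c_n, need_multi=True, what="common-bifunctional")
    switch_genes = pick(c_pool, n_switch, need_multi=False, what="category-switch")
    sw_lnc_a_genes = switch_genes[:sw_lnc_a]
    sw_lnc_b_genes = switch_genes[sw_lnc_a : sw_lnc_a + sw_lnc_b]
    sw_cod_a_genes = switch_genes[
        sw_lnc_a + sw_lnc_b : sw_lnc_a + sw_lnc_b + sw_cod_a
    ]
    sw_cod_b_genes = switch_genes[sw_lnc_a + sw_lnc_b + sw_cod_a :]

    n_identical = round(identical_set_frac * n_common)
    if n_identical < bif_c_n:
        raise ValueError(
            "identical_set_frac too small to also hold the common bifunctional genes"
        )
    # prefer single-isoform genes as identical-set hosts (they force sharing
    # anyway); common bifunctional genes sit inside the identical quota
    c_pool.sort(key=lambda g: len(catalog.genes[g]))
    identical_plain = c_pool[: n_identical - bif_c_n]
    ordinary_common = c_pool[n_identical - bif_c_n :]
    identical_genes = bif_c_genes + identical_plain

    sets_a: Dict[str, List[TranscriptModel]] = {}
    sets_b: Dict[str, List[TranscriptModel]] = {}

    def mark(ts: Sequence[TranscriptModel], coding: bool) -> None:
        for t in ts:
            if t.transcript_id not in truth.coding_label:
                truth.coding_label[t.transcript_id] = coding
                truth.coding_scores[t.transcript_id] = float(
                    rng.uniform(0.5, 6.0) if coding else rng.uniform(-6.0, -0.5)
                )

    def force_noncoding(ts: Sequence[TranscriptModel]) -> None:
        for t in ts:
            truth.coding_label[t.transcript_id] = False
            if truth.coding_scores.get(t.transcript_id, -1.0) > 0:
                truth.coding_scores[t.transcript_id] = float(rng.uniform(-6.0, -0.5))

    def expressed_subset(gid: str) -> List[TranscriptModel]:
        ts = catalog.genes[gid]
        m = min(_draw(expressed_per_gene, rng), len(ts))
        return list(ts[:m])

    # sample-exclusive ordinary genes: expressed subset, homogeneous label
    for gid in a_pool:
        sets_a[gid] = expressed_subset(gid)
        mark(sets_a[gid], bool(rng.random() < coding_frac))
    for gid in b_pool:
        sets_b[gid] = expressed_subset(gid)
        mark(sets_b[gid], bool(rng.random() < coding_frac))
    # exclusive bifunctional genes: one isoform coding, the rest noncoding
    for gid in bif_a_genes:
        ts = catalog.genes[gid]
        sets_a[gid] = list(ts)
        mark(ts[:1], True)
        mark(ts[1:], False)
        truth.bifunctional_a.add(gid)
    for gid in bif_b_genes:
        ts = catalog.genes[gid]
        sets_b[gid] = list(ts)
        mark(ts[:1], True)
        mark(ts[1:], False)
        truth.bifunctional_b.add(gid)
    # common bifunctional genes: identical sets, both classes, both samples
    for gid in bif_c_genes:
        ts = catalog.genes[gid]
        sets_a[gid] = list(ts)
        sets_b[gid] = list(ts)
        mark(ts[:1], True)
        mark(ts[1:], False)
        truth.bifunctional_a.add(gid)
        truth.bifunctional_b.add(gid)
    # identical-set (non-bifunctional) genes: same subset on both sides
    for gid in identical_plain:
        sub = expressed_subset(gid)
        sets_a[gid] = sub
        sets_b[gid] = list(sub)
        mark(sub, bool(rng.random() < coding_frac))
    # category-switch genes: the class-bearing isoform in one sample, a short
    # noncoding filler in the other
    for gid, kind in (
        *[(g, "lnc_a") for g in sw_lnc_a_genes],
        *[(g, "lnc_b") for g in sw_lnc_b_genes],
        *[(g, "cod_a") for g in sw_cod_a_genes],
        *[(g, "cod_b") for g in sw_cod_b_genes],
    ):
        coding = kind.startswith("cod")
        template = None
        for t in catalog.genes[gid]:
            if coding or t.spliced_length >= LNCRNA_MIN_LENGTH:
                template = t
                break
        if template is None:
            raise ValueError(
                f"gene {gid}: no isoform long enough to act as a long ncRNA"
            )
        filler = _short_filler(template, "short")
        mark([template], coding)
        mark([filler], False)
        if kind.endswith("_a"):
            sets_a[gid] = [template]
            sets_b[gid] = [filler]
        else:
            sets_b[gid] = [template]
            sets_a[gid] = [filler]
        {
            "lnc_a": truth.switch_lnc_a_only,
            "lnc_b": truth.switch_lnc_b_only,
            "cod_a": truth.switch_cod_a_only,
            "cod_b": truth.switch_cod_b_only,
        }[kind].add(gid)

    # planted splice variants on noncoding A-exclusive host genes (one per host)
    want = {
        SpliceClass.INTRON_RETENTION: n_splice_variants[0],
        SpliceClass.NOVEL_BOUNDARY_OR_EXON: n_splice_variants[1],
        SpliceClass.EXON_SKIPPING: n_splice_variants[2],
    }
    suffix = {
        SpliceClass.INTRON_RETENTION: "ret",
        SpliceClass.NOVEL_BOUNDARY_OR_EXON: "nov",
        SpliceClass.EXON_SKIPPING: "skip",
    }
    if sum(want.values()) > 0:
        planted = {cls: 0 for cls in want}
        for gid in a_pool:
            if all(planted[c] >= want[c] for c in want):
                break
            annotated = catalog.genes[gid]
            template = max(annotated, key=lambda t: t.num_exons)
            for cls in want:
                if planted[cls] >= want[cls]:
                    continue
                variant = _splice_variant(template, annotated, cls, suffix[cls])
                if variant is None:
                    continue
                # keep the host gene uniformly noncoding: no bifunctionality
                force_noncoding(sets_a[gid])
                mark([variant], False)
                sets_a[gid] = sets_a[gid] + [variant]
                truth.splice_class[variant.transcript_id] = cls
                planted[cls] += 1
        missing = {c.value: want[c] - planted[c] for c in want if planted[c] < want[c]}
        if missing:
            raise ValueError(f"could not plant requested splice variants: {missing}")

    # ordinary common genes realize the shared-isoform target.  Single-isoform
    # genes are forced to share their isoform (B differs via a filler).  Each
    # multi-isoform gene is either "shared-type" (A={t1,t2}, B={t1}: one
    # shared isoform) or "disjoint-type" (A={t1}, B={t2}: none); the number of
    # shared-type genes x solves  fixed + x = round(frac * |A isoforms|(x)).
    single = [g for g in ordinary_common if len(catalog.genes[g]) == 1]
    multi = [g for g in ordinary_common if len(catalog.genes[g]) >= 2]
    multi = [multi[i] for i in rng.permutation(len(multi))]
    base_a = sum(len(v) for v in sets_a.values())
    fixed_common = (
        sum(len(sets_a[g]) for g in identical_plain)
        + sum(len(sets_a[g]) for g in bif_c_genes)
        + len(single)
    )

    def iso_a_total(x: int) -> int:
        return base_a + len(single) + len(multi) + x

    x = 0
    for _ in range(1000):
        t = round(shared_isoform_frac * iso_a_total(x)) - fixed_common
        t = min(max(t, 0), len(multi))
        if t == x:
            break
        x = t
    target_common = round(shared_isoform_frac * iso_a_total(x))
    if target_common > fixed_common + len(multi):
        hi = (fixed_common + len(multi)) / iso_a_total(len(multi))
        raise ValueError(
            f"shared_isoform_frac={shared_isoform_frac} asks for more shared "
            f"isoforms than the common genes allow (max about {hi:.3f})"
        )
    # a target below fixed_common is structurally unreachable (identical-set
    # and single-isoform genes force that much sharing); x is clamped to 0 and
    # the realized fraction recorded in the ground truth
    for gid in single:
        t0 = catalog.genes[gid][0]
        filler = _short_filler(t0, "bshort")
        mark([t0], bool(rng.random() < coding_frac))
        mark([filler], False)
        sets_a[gid] = [t0]
        sets_b[gid] = [t0, filler]
    for i, gid in enumerate(multi):
        ts = catalog.genes[gid]
        coding = bool(rng.random() < coding_frac)
        if i < x:  # shared-type
            sets_a[gid] = [ts[0], ts[1]]
            sets_b[gid] = [ts[0]]
        else:  # disjoint-type
            sets_a[gid] = [ts[0]]
            sets_b[gid] = [ts[1]]
        mark(sets_a[gid] + sets_b[gid], coding)

    # assemble samples with RPKM values; the first transcript of each sample
    # sits exactly at the inclusive 0.1 threshold
    A = SampleTranscriptome(sample_a)
    B = SampleTranscriptome(sample_b)
    for sample, sets in ((A, sets_a), (B, sets_b)):
        all_ts = [t for gid in sorted(sets) for t in sets[gid]]
        vals = 0.1 + rng.lognormal(mean=np.log(5.0), sigma=1.0, size=len(all_ts))
        if len(vals):
            vals[0] = 0.1
        for t, rpkm in zip(all_ts, vals):
            sample.add(t, ExpressionRecord(t.transcript_id, float(rpkm)))

    truth.genes_common = set(common)
    truth.genes_a_only = set(a_only)
    truth.genes_b_only = set(b_only)
    truth.isoforms_a_total = len(A)
    truth.isoforms_b_total = len(B)
    truth.isoforms_common = sum(
        len(
            {t.transcript_id for t in sets_a.get(g, [])}
            & {t.transcript_id for t in sets_b.get(g, [])}
        )
        for g in common
    )
    truth.shared_gene_frac = n_common / n_genes if n_genes else 0.0
    truth.shared_isoform_frac = truth.isoforms_common / len(A) if len(A) else 0.0
    truth.identical_set_genes = set(identical_genes)
    return A, B, truth


def subthreshold_records(
    catalog: GeneCatalog,
    sample: SampleTranscriptome,
    seed: int = 0,
) -> List[ExpressionRecord]:
    """Sub-threshold (RPKM < 0.1) records for annotated transcripts the sample
    does not express, with a point mass at 0.0999 just below the boundary.

    Appending these to a sample's expression table makes the expressed-set
    filter's inclusive boundary observable end to end: filtering the combined
    table at 0.1 must give back exactly the planted expressed set.
    """
    rng = np.random.default_rng(seed)
    out: List[ExpressionRecord] = []
    for t in catalog:
        if t.transcript_id in sample:
            continue
        rpkm = 0.0999 if rng.random() < 0.3 else float(rng.uniform(0.0, 0.0998))
        out.append(ExpressionRecord(t.transcript_id, rpkm))
    return out


# ---------------------------------------------------------------------------
# conservation tracks
# ---------------------------------------------------------------------------


def generate_conservation_tracks(
    transcripts: Sequence[TranscriptModel],
    coverage_frac: float = 0.8,
    element_fraction: float = 0.2,
    clades: Sequence[str] = CLADES,
    seed: int = 0,
) -> Tuple[List[ConservationTrack], GroundTruth]:
    """Plant conserved elements under a known fraction of transcripts.

    For each clade, ``round(coverage_frac * n)`` transcripts receive one
    element inside their largest exon, sized to cover ``element_fraction`` of
    the transcript's exonic bases (capped at that exon's length).  Base scores
    are 0.95 exactly over planted elements and 0.2 over the remaining bases of
    those exons, so the >=0.9 criterion selects exactly the planted bases.

    Realized covered-transcript sets are recorded per clade by an explicit
    interval check over all supplied transcripts: when sibling isoforms share
    the exon an element was planted under, the sibling is covered too and the
    bookkeeping says so.  Pass one isoform per locus when the requested
    fraction must be realized exactly.
    """
    if not 0.0 <= coverage_frac <= 1.0:
        raise ValueError("coverage_frac must be in [0,1]")
    if not 0.0 < element_fraction <= 1.0:
        raise ValueError("element_fraction must be in (0,1]")
    rng = np.random.default_rng(seed)
    truth = GroundTruth(seed=seed)
    transcripts = list(transcripts)
    n = len(transcripts)
    tracks: List[ConservationTrack] = []
    for clade in clades:
        n_with = round(coverage_frac * n)
        order = rng.permutation(n)
        chosen = [transcripts[i] for i in order[:n_with]]
        elements: List[GenomicInterval] = []
        score_runs: Dict[str, List[Tuple[int, int, float]]] = {}
        for t in chosen:
            exon = max(t.exons, key=len)
            want = max(1, round(element_fraction * t.spliced_length))
            length = min(want, len(exon))
            start = exon.start + int(rng.integers(0, len(exon) - length + 1))
            el = GenomicInterval(t.chrom, start, start + length)
            elements.append(el)
            runs = score_runs.setdefault(t.chrom, [])
            runs.append((el.start, el.end, 0.95))
            if el.start > exon.start:
                runs.append((exon.start, el.start, 0.2))
            if el.end < exon.end:
                runs.append((el.end, exon.end, 0.2))
            truth.element_fraction[(t.transcript_id, clade)] = (
                length / t.spliced_length
            )
        covered: Set[str] = set()
        for t in transcripts:
            for el in elements:
                if any(ex.overlaps(el) for ex in t.exons):
                    covered.add(t.transcript_id)
                    break
        truth.covered_transcripts[clade] = covered
        truth.clade_coverage[clade] = len(covered) / n if n else 0.0
        for runs in score_runs.values():
            runs.sort()
        tracks.append(ConservationTrack(clade, score_runs, elements))
    return tracks, truth


# ---------------------------------------------------------------------------
# disease matrices
# ---------------------------------------------------------------------------


def generate_disease_matrices(
    n_probes: int = 200,
    n_case: int = 12,
    n_control: int = 12,
    de_frac: float = 0.1,
    effect_size: float = 4.0,
    corr_pairs: int = 5,
    rho: float = 0.66,
    seed: int = 0,
    base_mean: float = 6.0,
    base_sd: float = 1.0,
    corr_on_de: bool = False,
) -> Tuple[pd.DataFrame, pd.DataFrame, List[str], List[str], GroundTruth]:
    """Case/control expression with planted DE probes and correlated pairs.

    Expression is log-normal on the linear scale: log2(x+1) values are exactly
    Gaussian with mean ``base_mean`` and SD ``base_sd``, so a Welch test on
    log2(x+1) sees a clean ``effect_size``-SD mean shift for the planted DE
    probes (cases only).  ``corr_pairs`` extra gene-probe rows are generated
    bivariate-normal with a matching ncRNA probe at correlation ``rho`` on the
    log scale; the matched probes are non-DE by default, while ``corr_on_de``
    attaches them to planted DE probes (the gene probe is a linear function of
    the ncRNA probe plus independent noise, so the correlation is unaffected
    by the shift).

    Returns (ncrna_matrix, gene_matrix, case_samples, control_samples, truth);
    matrices are linear-scale, probes x samples.
    """
    if n_probes < 1 or n_case < 2 or n_control < 2:
        raise ValueError("need n_probes >= 1 and >= 2 samples per group")
    if not -1.0 < rho < 1.0:
        raise ValueError("|rho| must be < 1")
    if not 0.0 <= de_frac <= 1.0:
        raise ValueError("de_frac must be in [0,1]")
    rng = np.random.default_rng(seed)
    truth = GroundTruth(seed=seed, effect_size=effect_size, rho=rho)
    n_samples = n_case + n_control
    cases = [f"case{i + 1}" for i in range(n_case)]
    controls = [f"ctrl{i + 1}" for i in range(n_control)]
    samples = cases + controls

    z = rng.normal(base_mean, base_sd, size=(n_probes, n_samples))
    n_de = round(de_frac * n_probes)
    if corr_on_de:
        if corr_pairs > n_de:
            raise ValueError("corr_on_de requires at least corr_pairs DE probes")
    elif n_de + corr_pairs > n_probes:
        raise ValueError("de_frac and corr_pairs together exceed n_probes")
    de_idx = np.arange(n_de)
    z[de_idx, :n_case] += effect_size * base_sd
    probe_ids = [f"ncP{i + 1:04d}" for i in range(n_probes)]
    truth.de_probes = {probe_ids[i] for i in de_idx}

    # correlated gene probes ride on DE probes or on the last (non-DE) probes
    gene_ids = [f"geneP{j + 1:04d}" for j in range(corr_pairs)]
    gz = np.empty((corr_pairs, n_samples))
    for j in range(corr_pairs):
        i = j if corr_on_de else n_probes - corr_pairs + j
        x = (z[i] - base_mean) / base_sd
        noise = rng.normal(size=n_samples)
        gz[j] = base_mean + base_sd * (rho * x + math.sqrt(1 - rho * rho) * noise)
        truth.corr_pairs.append((probe_ids[i], gene_ids[j]))

    ncrna = pd.DataFrame(np.power(2.0, z) - 1.0, index=probe_ids, columns=samples)
    genes = pd.DataFrame(np.power(2.0, gz) - 1.0, index=gene_ids, columns=samples)
    return ncrna, genes, cases, controls, truth
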