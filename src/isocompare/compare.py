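"""Two-sample transcriptome comparison at gene and isoform resolution.

The central observation this module supports: two samples may share most of
their expressed *genes* while sharing only a minority of their expressed
*isoforms*, because common genes express different exon chains in each sample.
Operations here compute the gene/isoform overlap partitions, the genes whose
expressed isoform sets are exactly identical in both samples, genes that
switch coding category between samples, bifunctional-gene unions, and the
Table-style exon-count / isoforms-per-gene distributions.

Percentages are rounded half-up to two decimals for report parity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .coding import CodingAssessment, GeneCategory, GeneCodingCategory, TranscriptClass
from .model import SampleTranscriptome, TranscriptModel, exon_chain_key

__all__ = [
    "round_pct",
    "GeneOverlap",
    "IsoformOverlap",
    "CategorySwitches",
    "set_overlap",
    "compare_gene_sets",
    "isoform_key",
    "compare_isoform_sets",
    "identical_isoform_set_genes",
    "category_switch_genes",
    "bifunctional_union",
    "exon_count_bins",
    "isoforms_per_gene_bins",
    "multi_exon_share",
    "one_isoform_share",
    "mean_isoforms_per_gene",
    "distribution_tables",
    "ComparisonSummary",
]


def round_pct(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """Percentage 100*numerator/denominator rounded half-up to ``ndigits``."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-ndigits)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


def round_half_up(value: float, ndigits: int = 2) -> float:
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GeneOverlap:
    common: FrozenSet[str]
    a_only: FrozenSet[str]
    b_only: FrozenSet[str]
    pct_a_only: float
    pct_b_only: float

    @property
    def n_a(self) -> int:
        return len(self.common) + len(self.a_only)

    @property
    def n_b(self) -> int:
        return len(self.common) + len(self.b_only)


def set_overlap(
    a_ids: Iterable[str], b_ids: Iterable[str], allow_empty: bool = False
) -> GeneOverlap:
    """Partition two id sets into common / A-only / B-only with percentages.

    Works for any identifier universe (gene ids or isoform keys); the
    percentages are the sample-specific exclusive shares, e.g.
    ``100*|A-only|/|A|``.  An empty input set is an error unless
    ``allow_empty`` (sets can empty out when ambiguous keys are excluded);
    percentages over an empty side are reported as 0.
    """
    a, b = set(a_ids), set(b_ids)
    if (not a or not b) and not allow_empty:
        raise ValueError("both id sets must be non-empty")
    if not a or not b:
        return GeneOverlap(
            frozenset(a & b),
            frozenset(a - b),
            frozenset(b - a),
            pct_a_only=round_pct(len(a - b), len(a)) if a else 0.0,
            pct_b_only=round_pct(len(b - a), len(b)) if b else 0.0,
        )
    common = a & b
    a_only = a - b
    b_only = b - a
    return GeneOverlap(
        frozenset(common),
        frozenset(a_only),
        frozenset(b_only),
        pct_a_only=round_pct(len(a_only), len(a)),
        pct_b_only=round_pct(len(b_only), len(b)),
    )


def compare_gene_sets(A: SampleTranscriptome, B: SampleTranscriptome) -> GeneOverlap:
    """Gene-level overlap between two samples; identity is by gene_id alone.

    Genes present in both samples count as common even when none of their
    expressed isoforms coincide — the gene/isoform discrepancy is the point.
    """
    return set_overlap(A.gene_ids(), B.gene_ids())


def isoform_key(t: TranscriptModel, identity: str = "exon_chain") -> str:
    if identity == "exon_chain":
        return exon_chain_key(t)
    if identity == "transcript_id":
        return t.transcript_id
    raise ValueError(f"unknown isoform identity mode {identity!r}")


@dataclass(frozen=True)
class IsoformOverlap:
    common: FrozenSet[str]
    a_only: FrozenSet[str]
    b_only: FrozenSet[str]
    pct_a_only: float
    pct_b_only: float
    coding_counts: Dict[str, int] = field(default_factory=dict, compare=False)
    noncoding_counts: Dict[str, int] = field(default_factory=dict, compare=False)
    ambiguous_keys: FrozenSet[str] = frozenset()

    @property
    def n_a(self) -> int:
        return len(self.common) + len(self.a_only)

    @property
    def n_b(self) -> int:
        return len(self.common) + len(self.b_only)


def _keyed_isoforms(
    sample: SampleTranscriptome, identity: str
) -> Tuple[Dict[str, TranscriptModel], Set[str]]:
    """Key -> transcript map, plus keys shared by transcripts of different genes."""
    keyed: Dict[str, TranscriptModel] = {}
    ambiguous: Set[str] = set()
    for t in sample.transcripts():
        k = isoform_key(t, identity)
        if k in keyed and keyed[k].gene_id != t.gene_id:
            ambiguous.add(k)
        keyed[k] = t
    return keyed, ambiguous


def compare_isoform_sets(
    A: SampleTranscriptome,
    B: SampleTranscriptome,
    identity: str = "exon_chain",
    assessments_a: Optional[Mapping[str, CodingAssessment]] = None,
    assessments_b: Optional[Mapping[str, CodingAssessment]] = None,
) -> IsoformOverlap:
    """Isoform-level overlap between two samples.

    Identity is by exon-chain key by default (robust to transcript-id drift
    between quantifications) or by shared annotation id.  Keys claimed by
    transcripts of different genes are ambiguous: they are excluded from the
    partition and reported.  When coding assessments are supplied, each
    partition carries coding/noncoding sub-counts.
    """
    keyed_a, amb_a = _keyed_isoforms(A, identity)
    keyed_b, amb_b = _keyed_isoforms(B, identity)
    # cross-sample gene disagreement for the same key is also ambiguous
    ambiguous = amb_a | amb_b
    for k in keyed_a.keys() & keyed_b.keys():
        if keyed_a[k].gene_id != keyed_b[k].gene_id:
            ambiguous.add(k)
    set_a = set(keyed_a) - ambiguous
    set_b = set(keyed_b) - ambiguous
    base = set_overlap(set_a, set_b, allow_empty=True)

    coding_counts: Dict[str, int] = {}
    noncoding_counts: Dict[str, int] = {}
    if assessments_a is not None or assessments_b is not None:

        def is_coding(key: str) -> bool:
            for keyed, assessments in ((keyed_a, assessments_a), (keyed_b, assessments_b)):
                if key in keyed and assessments is not None:
                    a = assessments.get(keyed[key].transcript_id)
                    if a is not None:
                        return a.label == TranscriptClass.PROTEIN_CODING
            raise KeyError(f"no coding assessment for isoform key {key!r}")

        for name, keys in (
            ("common", base.common),
            ("a_only", base.a_only),
            ("b_only", base.b_only),
        ):
            n_cod = sum(1 for k in keys if is_coding(k))
            coding_counts[name] = n_cod
            noncoding_counts[name] = len(keys) - n_cod

    return IsoformOverlap(
        base.common,
        base.a_only,
        base.b_only,
        base.pct_a_only,
        base.pct_b_only,
        coding_counts,
        noncoding_counts,
        frozenset(ambiguous),
    )


def identical_isoform_set_genes(
    A: SampleTranscriptome, B: SampleTranscriptome, identity: str = "exon_chain"
) -> Set[str]:
    """Common genes whose expressed isoform sets are exactly equal in A and B
    (same number and identical structures)."""
    genes_a = A.transcripts_by_gene()
    genes_b = B.transcripts_by_gene()
    out: Set[str] = set()
    for gid in genes_a.keys() & genes_b.keys():
        keys_a = {isoform_key(t, identity) for t in genes_a[gid]}
        keys_b = {isoform_key(t, identity) for t in genes_b[gid]}
        if keys_a == keys_b:
            out.add(gid)
    return out


@dataclass(frozen=True)
class CategorySwitches:
    """Common genes that produce a transcript class in one sample only."""

    lncrna_a_only: FrozenSet[str]
    lncrna_b_only: FrozenSet[str]
    coding_a_only: FrozenSet[str]
    coding_b_only: FrozenSet[str]


def category_switch_genes(
    A: SampleTranscriptome,
    B: SampleTranscriptome,
    assessments_a: Mapping[str, CodingAssessment],
    assessments_b: Mapping[str, CodingAssessment],
) -> CategorySwitches:
    common = A.gene_ids() & B.gene_ids()

    def gene_flags(
        sample: SampleTranscriptome, assessments: Mapping[str, CodingAssessment]
    ) -> Dict[str, Tuple[bool, bool]]:
        flags: Dict[str, Tuple[bool, bool]] = {}
        for t in sample.transcripts():
            a = assessments[t.transcript_id]
            has_lnc, has_cod = flags.get(t.gene_id, (False, False))
            flags[t.gene_id] = (
                has_lnc or a.label == TranscriptClass.LONG_NCRNA,
                has_cod or a.label == TranscriptClass.PROTEIN_CODING,
            )
        return flags

    fa = gene_flags(A, assessments_a)
    fb = gene_flags(B, assessments_b)
    lnc_a = {g for g in common if fa[g][0] and not fb[g][0]}
    lnc_b = {g for g in common if fb[g][0] and not fa[g][0]}
    cod_a = {g for g in common if fa[g][1] and not fb[g][1]}
    cod_b = {g for g in common if fb[g][1] and not fa[g][1]}
    return CategorySwitches(
        frozenset(lnc_a), frozenset(lnc_b), frozenset(cod_a), frozenset(cod_b)
    )


def bifunctional_union(
    categories_a: Mapping[str, GeneCodingCategory],
    categories_b: Mapping[str, GeneCodingCategory],
) -> Tuple[Set[str], Set[str]]:
    """(union, intersection) of the bifunctional gene sets of two samples."""
    bif_a = {g for g, c in categories_a.items() if c.category == GeneCategory.BIFUNCTIONAL}
    bif_b = {g for g, c in categories_b.items() if c.category == GeneCategory.BIFUNCTIONAL}
    return bif_a | bif_b, bif_a & bif_b


# ---------------------------------------------------------------------------
# Table-style distributions
# ---------------------------------------------------------------------------

EXON_BIN_LABELS = ("1", "2", "3", "4", "5", "6+")
ISOFORM_BIN_LABELS = ("1", "2", "3", "4", "5", "6+")


def _bin_counts(values: Iterable[int]) -> Dict[str, int]:
    counts = Counter(values)
    bins = {label: 0 for label in EXON_BIN_LABELS}
    for v, n in counts.items():
        bins["6+" if v >= 6 else str(v)] += n
    return bins


def exon_count_bins(sample: SampleTranscriptome) -> Dict[str, int]:
    """Transcript counts binned by exon number {1,2,3,4,5,6+}."""
    return _bin_counts(t.num_exons for t in sample.transcripts())


def isoforms_per_gene_bins(sample: SampleTranscriptome) -> Dict[str, int]:
    """Gene counts binned by number of expressed isoforms {1,...,5,6+}."""
    return _bin_counts(len(ts) for ts in sample.transcripts_by_gene().values())


def multi_exon_share(exon_bins: Mapping[str, int]) -> float:
    """Percent of transcripts with two or more exons, from binned counts."""
    total = sum(exon_bins.values())
    multi = total - exon_bins.get("1", 0)
    return round_pct(multi, total)


def one_isoform_share(isoform_bins: Mapping[str, int]) -> float:
    """Percent of expressed genes with exactly one expressed isoform."""
    total = sum(isoform_bins.values())
    return round_pct(isoform_bins.get("1", 0), total)


def mean_isoforms_per_gene(n_isoforms: int, n_genes: int) -> float:
    """Average expressed isoforms per expressed gene, half-up to 2 decimals."""
    if n_genes < 1:
        raise ValueError("need at least one expressed gene")
    return round_half_up(n_isoforms / n_genes)


@dataclass
class ComparisonSummary:
    """Everything the two-sample report prints, in one bundle."""

    sample_a: str
    sample_b: str
    exon_bins_a: Dict[str, int]
    exon_bins_b: Dict[str, int]
    isoform_bins_a: Dict[str, int]
    isoform_bins_b: Dict[str, int]
    multi_exon_pct_a: float
    multi_exon_pct_b: float
    one_isoform_pct_a: float
    one_isoform_pct_b: float
    mean_isoforms_a: float
    mean_isoforms_b: float
    gene_overlap: GeneOverlap
    isoform_overlap: IsoformOverlap
    identical_set_genes: Set[str]
    switches: Optional[CategorySwitches] = None
    bifunctional_union_genes: Optional[Set[str]] = None
    bifunctional_common_genes: Optional[Set[str]] = None

    def to_dict(self) -> Dict[str, object]:
        d: Dict[str, object] = {
            "sample_a": self.sample_a,
            "sample_b": self.sample_b,
            "exon_bins_a": self.exon_bins_a,
            "exon_bins_b": self.exon_bins_b,
            "isoform_bins_a": self.isoform_bins_a,
            "isoform_bins_b": self.isoform_bins_b,
            "multi_exon_pct_a": self.multi_exon_pct_a,
            "multi_exon_pct_b": self.multi_exon_pct_b,
            "one_isoform_pct_a": self.one_isoform_pct_a,
            "one_isoform_pct_b": self.one_isoform_pct_b,
            "mean_isoforms_a": self.mean_isoforms_a,
            "mean_isoforms_b": self.mean_isoforms_b,
            "genes_common": len(self.gene_overlap.common),
            "genes_a_only": len(self.gene_overlap.a_only),
            "genes_b_only": len(self.gene_overlap.b_only),
            "genes_pct_a_only": self.gene_overlap.pct_a_only,
            "genes_pct_b_only": self.gene_overlap.pct_b_only,
            "isoforms_common": len(self.isoform_overlap.common),
            "isoforms_a_only": len(self.isoform_overlap.a_only),
            "isoforms_b_only": len(self.isoform_overlap.b_only),
            "isoforms_pct_a_only": self.isoform_overlap.pct_a_only,
            "isoforms_pct_b_only": self.isoform_overlap.pct_b_only,
            "identical_isoform_set_genes": len(self.identical_set_genes),
        }
        if self.switches is not None:
            d.update(
                lncrna_a_only_genes=len(self.switches.lncrna_a_only),
                lncrna_b_only_genes=len(self.switches.lncrna_b_only),
                coding_a_only_genes=len(self.switches.coding_a_only),
                coding_b_only_genes=len(self.switches.coding_b_only),
            )
        if self.bifunctional_union_genes is not None:
            d["bifunctional_union"] = len(self.bifunctional_union_genes)
            d["bifunctional_common"] = len(self.bifunctional_common_genes or set())
        return d


def distribution_tables(sample: SampleTranscriptome) -> Dict[str, object]:
    """Per-sample Table-style fragments: exon and isoform histograms plus the
    derived shares and the isoforms-per-gene mean."""
    exon_bins = exon_count_bins(sample)
    iso_bins = isoforms_per_gene_bins(sample)
    return {
        "exon_bins": exon_bins,
        "isoform_bins": iso_bins,
        "multi_exon_pct": multi_exon_share(exon_bins),
        "one_isoform_pct": one_isoform_share(iso_bins),
        "mean_isoforms_per_gene": mean_isoforms_per_gene(
            len(sample), len(sample.gene_ids())
        ),
        "n_transcripts": len(sample),
        "n_genes": len(sample.gene_ids()),
    }


def summarize_comparison(
    A: SampleTranscriptome,
    B: SampleTranscriptome,
    identity: str = "exon_chain",
    assessments_a: Optional[Mapping[str, CodingAssessment]] = None,
    assessments_b: Optional[Mapping[str, CodingAssessment]] = None,
    categories_a: Optional[Mapping[str, GeneCodingCategory]] = None,
    categories_b: Optional[Mapping[str, GeneCodingCategory]] = None,
) -> ComparisonSummary:
    exon_a, exon_b = exon_count_bins(A), exon_count_bins(B)
    iso_a, iso_b = isoforms_per_gene_bins(A), isoforms_per_gene_bins(B)
    summary = ComparisonSummary(
        sample_a=A.sample_name,
        sample_b=B.sample_name,
        exon_bins_a=exon_a,
        exon_bins_b=exon_b,
        isoform_bins_a=iso_a,
        isoform_bins_b=iso_b,
        multi_exon_pct_a=multi_exon_share(exon_a),
        multi_exon_pct_b=multi_exon_share(exon_b),
        one_isoform_pct_a=one_isoform_share(iso_a),
        one_isoform_pct_b=one_isoform_share(iso_b),
        mean_isoforms_a=mean_isoforms_per_gene(len(A), len(A.gene_ids())),
        mean_isoforms_b=mean_isoforms_per_gene(len(B), len(B.gene_ids())),
        gene_overlap=compare_gene_sets(A, B),
        isoform_overlap=compare_isoform_sets(
            A, B, identity, assessments_a, assessments_b
        ),
        identical_set_genes=identical_isoform_set_genes(A, B, identity),
    )
    if assessments_a is not None and assessments_b is not None:
        summary.switches = category_switch_genes(A, B, assessments_a, assessments_b)
    if categories_a is not None and categories_b is not None:
        union, common = bifunctional_union(categories_a, categories_b)
        summary.bifunctional_union_genes = union
        summary.bifunctional_common_genes = common
    return summary
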