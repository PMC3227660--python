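"""Core domain types: genomic intervals, transcript models and sample transcriptomes.

All coordinates are 0-based half-open throughout the package; conversion to and
from 1-based closed conventions (GTF) happens only in :mod:`isocompare.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Tuple

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "GeneCatalog",
    "ExpressionRecord",
    "SampleTranscriptome",
    "exon_chain_key",
    "chains_match",
    "extract_transcript_sequence",
    "reverse_complement",
    "clean_sequence",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_VALID_BASES = frozenset("ACGTN")


def clean_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and validate its alphabet (A/C/G/T/N)."""
    s = seq.upper()
    if not s:
        raise ValueError("empty nucleotide sequence")
    bad = set(s) - _VALID_BASES
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)!r}")
    return s


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True when *other* lies strictly inside this interval (both ends)."""
        return (
            self.chrom == other.chrom
            and self.start < other.start
            and other.end < self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """One isoform: an ordered, strand-aware exon chain on one chromosome.

    Exons must be sorted by start, pairwise non-overlapping, and separated by
    at least one base (adjacent exons would be a single exon).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: zero exons")
        object.__setattr__(self, "exons", tuple(self.exons))
        prev_end: Optional[int] = None
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon on {ex.chrom} "
                    f"but transcript on {self.chrom}"
                )
            if prev_end is not None and ex.start <= prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons must be sorted, "
                    "non-overlapping and non-adjacent"
                )
            prev_end = ex.end

    @property
    def spliced_length(self) -> int:
        return sum(len(ex) for ex in self.exons)

    @property
    def num_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end)

    @property
    def introns(self) -> Tuple[GenomicInterval, ...]:
        """Gaps between consecutive exons, in genomic order."""
        return tuple(
            GenomicInterval(self.chrom, a.end, b.start)
            for a, b in zip(self.exons, self.exons[1:])
        )

    def internal_boundaries(self) -> Tuple[int, ...]:
        """All exon starts/ends except the first exon start and last exon end.

        Transcript termini are excluded because assembled 5'/3' ends are not
        splice sites.
        """
        bounds: List[int] = []
        for ex in self.exons:
            bounds.extend((ex.start, ex.end))
        return tuple(bounds[1:-1])


def exon_chain_key(t: TranscriptModel) -> str:
    """Canonical key for structural isoform identity.

    Two transcripts get the same key iff they share chromosome, strand and the
    full ordered exon chain, terminal ends included.
    """
    coords = ",".join(f"{ex.start}-{ex.end}" for ex in t.exons)
    return f"{t.chrom}({t.strand}){coords}"


def chains_match(a: TranscriptModel, b: TranscriptModel, terminal_tolerance: int = 0) -> bool:
    """Exon-chain equality with an optional slack on the two transcript termini.

    With ``terminal_tolerance=0`` this is exact identity (same as comparing
    :func:`exon_chain_key`).  A positive tolerance allows the first exon start
    and the last exon end to differ by up to that many bases — useful for
    assembled transcripts whose termini are imprecise — while all internal
    splice boundaries must still match exactly.
    """
    if (a.chrom, a.strand, a.num_exons) != (b.chrom, b.strand, b.num_exons):
        return False
    if a.internal_boundaries() != b.internal_boundaries():
        return False
    return (
        abs(a.exons[0].start - b.exons[0].start) <= terminal_tolerance
        and abs(a.exons[-1].end - b.exons[-1].end) <= terminal_tolerance
    )


def extract_transcript_sequence(
    genome: Mapping[str, str], t: TranscriptModel
) -> str:
    """Spliced transcript sequence: exon substrings concatenated in genomic
    order, reverse-complemented as a whole for minus-strand transcripts."""
    if t.chrom not in genome:
        raise KeyError(f"chromosome {t.chrom!r} not in genome")
    chrom_seq = genome[t.chrom]
    n = len(chrom_seq)
    parts: List[str] = []
    for ex in t.exons:
        if ex.end > n:
            raise ValueError(
                f"transcript {t.transcript_id}: exon {ex.start}-{ex.end} beyond "
                f"end of {t.chrom} (length {n})"
            )
        parts.append(chrom_seq[ex.start : ex.end])
    seq = "".join(parts)
    if t.strand == "-":
        seq = reverse_complement(seq)
    return seq


class GeneCatalog:
    """Annotated transcripts grouped by gene, with unique transcript ids."""

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()) -> None:
        self.genes: Dict[str, List[TranscriptModel]] = {}
        self._by_tid: Dict[str, TranscriptModel] = {}
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self._by_tid:
            raise ValueError(f"duplicate transcript_id {t.transcript_id!r}")
        self._by_tid[t.transcript_id] = t
        self.genes.setdefault(t.gene_id, []).append(t)

    def __len__(self) -> int:
        return len(self._by_tid)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._by_tid

    def __iter__(self) -> Iterator[TranscriptModel]:
        for gid in self.genes:
            yield from self.genes[gid]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def transcript(self, transcript_id: str) -> TranscriptModel:
        return self._by_tid[transcript_id]

    def transcripts_of(self, gene_id: str) -> List[TranscriptModel]:
        return list(self.genes.get(gene_id, []))


@dataclass(frozen=True)
class ExpressionRecord:
    """Expression of one transcript: raw exon read count and/or RPKM."""

    transcript_id: str
    rpkm: float
    read_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.rpkm < 0:
            raise ValueError(f"{self.transcript_id}: negative rpkm")
        if self.read_count is not None and self.read_count < 0:
            raise ValueError(f"{self.transcript_id}: negative read count")


@dataclass
class SampleTranscriptome:
    """Named set of expressed transcripts with their expression records."""

    sample_name: str
    records: Dict[str, Tuple[TranscriptModel, ExpressionRecord]] = field(
        default_factory=dict
    )

    def add(self, t: TranscriptModel, rec: ExpressionRecord) -> None:
        if t.transcript_id in self.records:
            raise ValueError(
                f"{self.sample_name}: duplicate transcript_id {t.transcript_id!r}"
            )
        if rec.transcript_id != t.transcript_id:
            raise ValueError("transcript/record id mismatch")
        self.records[t.transcript_id] = (t, rec)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.records

    def transcripts(self) -> List[TranscriptModel]:
        return [t for t, _ in self.records.values()]

    def gene_ids(self) -> set:
        return {t.gene_id for t, _ in self.records.values()}

    def transcripts_by_gene(self) -> Dict[str, List[TranscriptModel]]:
        out: Dict[str, List[TranscriptModel]] = {}
        for t, _ in self.records.values():
            out.setdefault(t.gene_id, []).append(t)
        return out
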