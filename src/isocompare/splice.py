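"""Splice-structure classification of a transcript against its gene annotation.

A query transcript (typically an assembled long ncRNA) is compared with all
annotated isoforms of its gene and assigned exactly one class:

1. IDENTICAL — the exon chain equals some annotated isoform's chain;
2. INTRON_RETENTION — an exon of the query fully engulfs an annotated intron
   (both splice sites of that intron strictly inside the exon);
3. NOVEL_BOUNDARY_OR_EXON — an internal splice boundary of the query matches
   no annotated exon boundary of the gene, or an exon of the query overlaps no
   annotated exon at all (a new exon);
4. EXON_SKIPPING — anything else: the chain differs from every annotated
   isoform, yet every internal boundary is annotated and no intron is
   retained, i.e. the query dropped internal exon(s).

The precedence retention > novel > skipping makes the classes disjoint;
retention is the most structurally specific signal, so it wins ties.  The
transcript's own terminal ends (first exon start, last exon end) are never
treated as splice boundaries, because assembled 5'/3' ends are unreliable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Sequence, Set, Tuple

from .model import GeneCatalog, TranscriptModel, exon_chain_key

__all__ = ["SpliceClass", "classify_splice_structure", "tally_splice_classes", "SpliceTally"]


class SpliceClass(str, Enum):
    IDENTICAL = "IDENTICAL"
    INTRON_RETENTION = "INTRON_RETENTION"
    NOVEL_BOUNDARY_OR_EXON = "NOVEL_BOUNDARY_OR_EXON"
    EXON_SKIPPING = "EXON_SKIPPING"


def classify_splice_structure(
    t: TranscriptModel, annotated: Sequence[TranscriptModel]
) -> SpliceClass:
    if not annotated:
        raise ValueError("annotated isoform list must be non-empty")
    for ann in annotated:
        if ann.gene_id != t.gene_id:
            raise ValueError(
                f"gene mismatch: query {t.gene_id!r} vs annotated {ann.gene_id!r}"
            )
        if ann.chrom != t.chrom or ann.strand != t.strand:
            raise ValueError(
                f"transcript {t.transcript_id}: chrom/strand mismatch with annotation"
            )

    key = exon_chain_key(t)
    if any(exon_chain_key(ann) == key for ann in annotated):
        return SpliceClass.IDENTICAL

    annotated_introns = {
        (iv.start, iv.end) for ann in annotated for iv in ann.introns
    }
    for ex in t.exons:
        for s, e in annotated_introns:
            if ex.start < s and e < ex.end:
                return SpliceClass.INTRON_RETENTION

    boundary_set: Set[int] = set()
    annotated_exons: List[Tuple[int, int]] = []
    for ann in annotated:
        for ex in ann.exons:
            boundary_set.add(ex.start)
            boundary_set.add(ex.end)
            annotated_exons.append((ex.start, ex.end))
    if any(b not in boundary_set for b in t.internal_boundaries()):
        return SpliceClass.NOVEL_BOUNDARY_OR_EXON
    for ex in t.exons:
        if not any(ex.start < e and s < ex.end for s, e in annotated_exons):
            return SpliceClass.NOVEL_BOUNDARY_OR_EXON

    return SpliceClass.EXON_SKIPPING


@dataclass
class SpliceTally:
    counts: Dict[SpliceClass, int]
    excluded: List[str]  # transcript ids with no annotated gene

    @property
    def total_classified(self) -> int:
        return sum(self.counts.values())

    @property
    def total_non_identical(self) -> int:
        return self.total_classified - self.counts.get(SpliceClass.IDENTICAL, 0)


def tally_splice_classes(
    transcripts: Iterable[TranscriptModel], catalog: GeneCatalog
) -> SpliceTally:
    """Classify each transcript against its gene's annotated isoforms and
    count the classes; transcripts of unannotated genes are reported and
    excluded rather than guessed at."""
    counts: Counter = Counter()
    excluded: List[str] = []
    for t in transcripts:
        annotated = catalog.transcripts_of(t.gene_id)
        if not annotated:
            excluded.append(t.transcript_id)
            continue
        counts[classify_splice_structure(t, annotated)] += 1
    full = {cls: counts.get(cls, 0) for cls in SpliceClass}
    return SpliceTally(full, excluded)
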