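"""Per-transcript conservation against base-score tracks and conserved elements.

Conservation is evaluated over exonic (spliced) bases only: the objects of
interest are transcripts, not loci, so intronic bases never contribute.  Two
statistics are computed per transcript and clade:

* ``base_conserved_fraction`` — fraction of exonic bases whose per-base score
  (phastCons-style, in [0,1]) is at least the cutoff (default 0.9); bases
  absent from the track count as score 0 by default (score dumps omit
  unscored bases), with an option to exclude missing bases instead;
* ``element_overlap_ratio`` — fraction of exonic bases covered by predicted
  conserved elements (interval arithmetic over merged elements).

``contains_element`` is true as soon as at least one exonic base is covered.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .model import GenomicInterval, TranscriptModel

__all__ = [
    "ConservationTrack",
    "ConservationSummary",
    "merge_intervals",
    "base_conserved_fraction",
    "element_overlap_ratio",
    "clade_conservation_summary",
    "CLADES",
    "DEFAULT_SCORE_CUTOFF",
]

CLADES = ("vertebrates46", "placental33", "primates10")
DEFAULT_SCORE_CUTOFF = 0.9

ScoreRuns = Dict[str, List[Tuple[int, int, float]]]  # chrom -> sorted (start, end, score)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> Dict[str, List[Tuple[int, int]]]:
    """Sort and merge intervals per chromosome into disjoint (start, end) runs."""
    per_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for iv in intervals:
        per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, ivs in per_chrom.items():
        ivs.sort()
        out: List[Tuple[int, int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[chrom] = out
    return merged


@dataclass
class ConservationTrack:
    """One clade's per-base score runs plus its predicted conserved elements."""

    clade: str
    score_runs: ScoreRuns = field(default_factory=dict)
    elements: List[GenomicInterval] = field(default_factory=list)
    _merged: Optional[Dict[str, List[Tuple[int, int]]]] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        for chrom, runs in self.score_runs.items():
            runs.sort()
            for s, e, score in runs:
                if not (0.0 <= score <= 1.0):
                    raise ValueError(
                        f"{self.clade}/{chrom}: score {score} outside [0,1]"
                    )
                if s >= e:
                    raise ValueError(f"{self.clade}/{chrom}: empty score run")

    @property
    def merged_elements(self) -> Dict[str, List[Tuple[int, int]]]:
        if self._merged is None:
            self._merged = merge_intervals(self.elements)
        return self._merged


@dataclass(frozen=True)
class ConservationSummary:
    transcript_id: str
    clade: str
    base_conserved_fraction: float
    element_overlap_ratio: float
    contains_element: bool
    missing_chrom: bool = False


def _overlap_bases(exon: GenomicInterval, runs: Sequence[Tuple[int, int]]) -> int:
    """Bases of ``exon`` covered by sorted disjoint (start, end) runs."""
    if not runs:
        return 0
    total = 0
    starts = [r[0] for r in runs]
    i = max(bisect_right(starts, exon.start) - 1, 0)
    while i < len(runs) and runs[i][0] < exon.end:
        s, e = runs[i][0], runs[i][1]
        total += max(0, min(e, exon.end) - max(s, exon.start))
        i += 1
    return total


def base_conserved_fraction(
    t: TranscriptModel,
    track: ConservationTrack,
    cutoff: float = DEFAULT_SCORE_CUTOFF,
    missing_as_zero: bool = True,
) -> float:
    """Fraction of exonic bases scoring at least ``cutoff`` in the track.

    With ``missing_as_zero=False``, bases the track does not cover are
    excluded from the denominator instead of counting as unconserved; a
    transcript with no scored base then gets 0.0.
    """
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError("cutoff must be in [0,1]")
    runs = track.score_runs.get(t.chrom, [])
    passing = [(s, e) for s, e, score in runs if score >= cutoff]
    conserved = sum(_overlap_bases(ex, passing) for ex in t.exons)
    if missing_as_zero:
        denom = t.spliced_length
    else:
        covered = [(s, e) for s, e, _ in runs]
        denom = sum(_overlap_bases(ex, covered) for ex in t.exons)
        if denom == 0:
            return 0.0
    return conserved / denom


def element_overlap_ratio(
    t: TranscriptModel, elements: Mapping[str, Sequence[Tuple[int, int]]]
) -> float:
    """Fraction of exonic bases covered by merged conserved elements."""
    runs = elements.get(t.chrom, [])
    covered = sum(_overlap_bases(ex, runs) for ex in t.exons)
    return covered / t.spliced_length


def clade_conservation_summary(
    transcripts: Iterable[TranscriptModel],
    tracks: Sequence[ConservationTrack],
    cutoff: float = DEFAULT_SCORE_CUTOFF,
    min_overlap_bases: int = 1,
) -> Tuple[List[ConservationSummary], Dict[str, float]]:
    """Per-transcript conservation rows for every clade plus, per clade, the
    fraction of transcripts containing at least one conserved element.

    ``min_overlap_bases`` is the minimum element overlap (in bases) for
    ``contains_element``; the default 1 means any overlap counts.
    """
    if not tracks:
        raise ValueError("need at least one clade track")
    transcripts = list(transcripts)
    rows: List[ConservationSummary] = []
    aggregate: Dict[str, float] = {}
    for track in tracks:
        n_with = 0
        for t in transcripts:
            missing = (
                t.chrom not in track.score_runs and t.chrom not in track.merged_elements
            )
            frac = base_conserved_fraction(t, track, cutoff)
            ratio = element_overlap_ratio(t, track.merged_elements)
            contains = ratio * t.spliced_length >= min_overlap_bases - 1e-9 and ratio > 0
            if contains:
                n_with += 1
            rows.append(
                ConservationSummary(
                    t.transcript_id, track.clade, frac, ratio, contains, missing
                )
            )
        aggregate[track.clade] = n_with / len(transcripts) if transcripts else 0.0
    return rows, aggregate
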