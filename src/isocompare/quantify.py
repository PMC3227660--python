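"""RPKM computation and the expressed-set filter.

RPKM = 10^9 * C / (N * L) with C the exon reads of the transcript, N the total
mapped reads of the library and L the spliced transcript length in bases.  A
transcript counts as expressed when its RPKM is greater than or equal to the
threshold (default 0.1, inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

from .model import ExpressionRecord, SampleTranscriptome, TranscriptModel

__all__ = [
    "LibrarySize",
    "compute_rpkm",
    "resolve_expression",
    "filter_expressed",
    "FilterReport",
    "DEFAULT_MIN_RPKM",
]

DEFAULT_MIN_RPKM = 0.1


@dataclass(frozen=True)
class LibrarySize:
    """Total mapped reads N of a sequencing library."""

    total_mapped_reads: int

    def __post_init__(self) -> None:
        if self.total_mapped_reads < 1:
            raise ValueError("library size must be >= 1 mapped read")


def compute_rpkm(read_count: int, library: LibrarySize, spliced_length: int) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if spliced_length < 1:
        raise ValueError("spliced_length must be >= 1")
    if read_count < 0:
        raise ValueError("read_count must be non-negative")
    return 1e9 * read_count / (library.total_mapped_reads * spliced_length)


def resolve_expression(
    records: Iterable[ExpressionRecord],
    transcripts: Dict[str, TranscriptModel],
    library: Optional[LibrarySize] = None,
    rel_tol: float = 1e-6,
) -> List[ExpressionRecord]:
    """Fill in RPKM from counts where needed, cross-checking supplied values.

    When a record carries both a read count and a precomputed RPKM and a
    library size is known, the two must agree to ``rel_tol`` relative error;
    upstream quantifiers are not re-run, so a disagreement is treated as a
    data error rather than silently preferring one source.
    """
    out: List[ExpressionRecord] = []
    for rec in records:
        if rec.transcript_id not in transcripts:
            raise KeyError(f"expression for unknown transcript {rec.transcript_id!r}")
        t = transcripts[rec.transcript_id]
        if rec.read_count is not None and library is not None:
            computed = compute_rpkm(rec.read_count, library, t.spliced_length)
            if rec.rpkm > 0:
                denom = max(abs(computed), abs(rec.rpkm))
                if denom > 0 and not math.isclose(
                    computed, rec.rpkm, rel_tol=rel_tol, abs_tol=0.0
                ):
                    raise ValueError(
                        f"{rec.transcript_id}: supplied rpkm {rec.rpkm} inconsistent "
                        f"with counts ({computed:.6g} from C={rec.read_count})"
                    )
            rec = ExpressionRecord(rec.transcript_id, computed, rec.read_count)
        out.append(rec)
    return out


@dataclass(frozen=True)
class FilterReport:
    retained: int
    dropped: int
    threshold: float


def filter_expressed(
    records: Iterable[Tuple[TranscriptModel, ExpressionRecord]],
    threshold: float = DEFAULT_MIN_RPKM,
    sample_name: str = "sample",
) -> Tuple[SampleTranscriptome, FilterReport]:
    """Keep transcripts with RPKM >= threshold (inclusive boundary).

    Returns the expressed set plus a report of retained/dropped counts.
    Duplicate transcript ids are an error (the input is one quantification of
    one sample).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    sample = SampleTranscriptome(sample_name)
    dropped = 0
    seen = set()
    for t, rec in records:
        if t.transcript_id in seen:
            raise ValueError(f"duplicate transcript_id {t.transcript_id!r}")
        seen.add(t.transcript_id)
        if rec.rpkm >= threshold:
            sample.add(t, rec)
        else:
            dropped += 1
    return sample, FilterReport(len(sample), dropped, threshold)
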