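"""Coding-potential labelling of transcripts and gene-level coding categories.

Transcripts come with a CPC-style coding score (positive means the sequence
looks protein-coding).  The three-way transcript class is:

* PROTEIN_CODING — score above the cutoff (default 0);
* LONG_NCRNA — noncoding and spliced length strictly greater than 200 nt;
* SHORT_NCRNA — noncoding and spliced length of 200 nt or less.

A gene is *bifunctional* when its expressed isoforms include at least one
protein-coding transcript and at least one long ncRNA.  Short noncoding
isoforms do not confer bifunctionality: the biological claim is about genes
producing both proteins and long regulatory RNAs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Mapping

from .model import SampleTranscriptome, TranscriptModel

__all__ = [
    "TranscriptClass",
    "GeneCategory",
    "CodingAssessment",
    "GeneCodingCategory",
    "label_coding",
    "classify_transcript",
    "classify_gene",
    "classify_sample",
    "LNCRNA_MIN_LENGTH",
]

# a long ncRNA must be strictly longer than 200 nt
LNCRNA_MIN_LENGTH = 201


class TranscriptClass(str, Enum):
    PROTEIN_CODING = "PROTEIN_CODING"
    LONG_NCRNA = "LONG_NCRNA"
    SHORT_NCRNA = "SHORT_NCRNA"


class GeneCategory(str, Enum):
    CODING_ONLY = "CODING_ONLY"
    NCRNA_ONLY = "NCRNA_ONLY"
    BIFUNCTIONAL = "BIFUNCTIONAL"


@dataclass(frozen=True)
class CodingAssessment:
    transcript_id: str
    gene_id: str
    score: float
    label: TranscriptClass


@dataclass(frozen=True)
class GeneCodingCategory:
    gene_id: str
    category: GeneCategory


def label_coding(score: float, cutoff: float = 0.0) -> str:
    """Binary coding call from a CPC-style score: coding iff score > cutoff.

    A score exactly at the cutoff is noncoding (CPC labels positive scores as
    coding).
    """
    if not math.isfinite(score):
        raise ValueError(f"non-finite coding score {score!r}")
    return "coding" if score > cutoff else "noncoding"


def classify_transcript(
    t: TranscriptModel, score: float, cutoff: float = 0.0
) -> CodingAssessment:
    if label_coding(score, cutoff) == "coding":
        label = TranscriptClass.PROTEIN_CODING
    elif t.spliced_length >= LNCRNA_MIN_LENGTH:
        label = TranscriptClass.LONG_NCRNA
    else:
        label = TranscriptClass.SHORT_NCRNA
    return CodingAssessment(t.transcript_id, t.gene_id, score, label)


def classify_gene(assessments: Iterable[CodingAssessment]) -> GeneCodingCategory:
    """Category of one gene from the assessments of its expressed isoforms."""
    assessments = list(assessments)
    if not assessments:
        raise ValueError("classify_gene needs at least one assessment")
    gene_ids = {a.gene_id for a in assessments}
    if len(gene_ids) != 1:
        raise ValueError(f"assessments span multiple genes: {sorted(gene_ids)}")
    gene_id = assessments[0].gene_id
    labels = {a.label for a in assessments}
    has_coding = TranscriptClass.PROTEIN_CODING in labels
    has_lnc = TranscriptClass.LONG_NCRNA in labels
    if has_coding and has_lnc:
        category = GeneCategory.BIFUNCTIONAL
    elif has_coding:
        category = GeneCategory.CODING_ONLY
    else:
        category = GeneCategory.NCRNA_ONLY
    return GeneCodingCategory(gene_id, category)


def classify_sample(
    sample: SampleTranscriptome,
    scores: Mapping[str, float],
    cutoff: float = 0.0,
) -> tuple[Dict[str, CodingAssessment], Dict[str, GeneCodingCategory]]:
    """Per-transcript assessments and per-gene categories for one sample."""
    assessments: Dict[str, CodingAssessment] = {}
    for t, _rec in sample.records.values():
        if t.transcript_id not in scores:
            raise KeyError(f"no coding score for transcript {t.transcript_id!r}")
        assessments[t.transcript_id] = classify_transcript(
            t, scores[t.transcript_id], cutoff
        )
    by_gene: Dict[str, List[CodingAssessment]] = {}
    for a in assessments.values():
        by_gene.setdefault(a.gene_id, []).append(a)
    categories = {gid: classify_gene(items) for gid, items in by_gene.items()}
    return assessments, categories
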