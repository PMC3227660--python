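"""Disease-association screen for long ncRNAs.

Three steps, mirroring how array probes are repurposed to report on
transcripts that have no probe set of their own:

1. probe matching — a short oligo probe represents a transcript iff its
   sequence occurs as an exact substring of exactly one transcript's spliced
   sequence across the whole target set ("exact and unique");
2. differential expression — per probe, a Welch two-sample t-test on
   log2(x+1) values between case and control samples, with Benjamini–Hochberg
   FDR control (default alpha 0.05);
3. correlation screen — Pearson correlation between matched ncRNA probes and
   gene probes across samples; a hit needs |r| >= 0.4 and p < 0.05 (r
   threshold inclusive, p threshold exclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import TranscriptModel, reverse_complement

__all__ = [
    "Probe",
    "ProbeMatch",
    "DEResult",
    "CorrelationHit",
    "match_probes",
    "differential_expression",
    "correlation_screen",
]


@dataclass(frozen=True)
class Probe:
    probe_id: str
    sequence: str
    gene_symbol: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"probe {self.probe_id}: empty sequence")
        if self.sequence != self.sequence.upper():
            raise ValueError(f"probe {self.probe_id}: sequence must be uppercase")


@dataclass(frozen=True)
class ProbeMatch:
    probe_id: str
    transcript_id: str
    offset: int  # 0-based offset within the spliced sequence
    unique: bool


@dataclass(frozen=True)
class DEResult:
    probe_id: str
    log2_mean_diff: float
    p_value: float
    q_value: float
    differential: bool
    constant: bool = False


@dataclass(frozen=True)
class CorrelationHit:
    ncrna_probe_id: str
    gene_probe_id: str
    gene_symbol: str
    r: float
    p_value: float


def _count_occurrences(haystack: str, needle: str) -> List[int]:
    """All (possibly overlapping) start offsets of needle in haystack."""
    offsets: List[int] = []
    start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return offsets
        offsets.append(i)
        start = i + 1


def match_probes(
    probes: Iterable[Probe],
    transcripts: Sequence[Tuple[TranscriptModel, str]],
    both_orientations: bool = False,
    require_gene_symbol_absent: bool = False,
) -> Tuple[List[ProbeMatch], Dict[str, str]]:
    """Exact-and-unique probe matching against spliced transcript sequences.

    A probe is reported iff the total number of its occurrence positions
    across all transcripts is exactly one.  ``both_orientations`` also scans
    the reverse complement of the probe (array design ambiguity);
    ``require_gene_symbol_absent`` pre-filters to probes without a gene symbol
    (probes annotated to known genes cannot stand for an unannotated ncRNA).

    Returns the matches plus a {probe_id: reason} map for excluded probes.
    """
    matches: List[ProbeMatch] = []
    rejected: Dict[str, str] = {}
    for probe in probes:
        if require_gene_symbol_absent and probe.gene_symbol:
            rejected[probe.probe_id] = "has gene symbol"
            continue
        needles = [probe.sequence]
        if both_orientations:
            rc = reverse_complement(probe.sequence)
            if rc != probe.sequence:
                needles.append(rc)
        hits: List[Tuple[str, int]] = []
        for t, seq in transcripts:
            for needle in needles:
                for off in _count_occurrences(seq, needle):
                    hits.append((t.transcript_id, off))
        if not hits:
            rejected[probe.probe_id] = "no match"
        elif len(hits) > 1:
            rejected[probe.probe_id] = f"non-unique ({len(hits)} occurrences)"
        else:
            tid, off = hits[0]
            matches.append(ProbeMatch(probe.probe_id, tid, off, unique=True))
    return matches, rejected


def differential_expression(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
    log_transform: bool = True,
) -> List[DEResult]:
    """Welch t-test per probe between two sample groups, BH-adjusted.

    ``matrix`` is probes x samples on the linear scale; values are log2(x+1)
    transformed first unless ``log_transform=False`` (already-logged input).
    Probes that are constant across all samples get p = 1 by convention and
    are flagged.  ``differential`` means q < alpha (strict).
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    missing = [s for s in group_a + group_b if s not in matrix.columns]
    if missing:
        raise KeyError(f"samples not in matrix: {missing}")
    x = matrix[group_a].to_numpy(dtype=float)
    y = matrix[group_b].to_numpy(dtype=float)
    if log_transform:
        if (x < 0).any() or (y < 0).any():
            raise ValueError("negative expression values under log2(x+1) transform")
        x = np.log2(x + 1.0)
        y = np.log2(y + 1.0)

    diff = x.mean(axis=1) - y.mean(axis=1)
    constant = (np.ptp(x, axis=1) == 0) & (np.ptp(y, axis=1) == 0) & (
        x[:, 0] == y[:, 0]
    )
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant rows trip scipy's near-identical-data warning; they are
        # handled explicitly below (p = 1 by convention)
        warnings.simplefilter("ignore", RuntimeWarning)
        _t, p = stats.ttest_ind(x, y, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    p[~np.isfinite(p)] = 1.0
    p[constant] = 1.0
    _rej, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    results = [
        DEResult(
            probe_id=str(pid),
            log2_mean_diff=float(d),
            p_value=float(pv),
            q_value=float(qv),
            differential=bool(qv < alpha),
            constant=bool(c),
        )
        for pid, d, pv, qv, c in zip(matrix.index, diff, p, q, constant)
    ]
    return results


def _pearson(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Pearson r with two-sided p from the t transform on n-2 df.

    r is computed as Sxy / sqrt(Sxx * Syy) (product under a single square
    root) so that exactly representable boundary correlations are not
    perturbed by intermediate rounding.
    """
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def correlation_screen(
    ncrna_rows: pd.DataFrame,
    gene_rows: pd.DataFrame,
    gene_symbols: Optional[Mapping[str, str]] = None,
    r_min: float = 0.4,
    p_max: float = 0.05,
    pairs: Optional[Iterable[Tuple[str, str]]] = None,
) -> Tuple[List[CorrelationHit], List[Tuple[str, str, str]]]:
    """Pearson screen of ncRNA probes against gene probes over shared samples.

    By default every (ncRNA probe, gene probe) pair is tested; ``pairs``
    restricts the screen.  Hits satisfy |r| >= r_min and p < p_max.
    Zero-variance vectors cannot be correlated: those pairs are skipped and
    reported as (ncrna, gene, reason).
    """
    samples = [c for c in ncrna_rows.columns if c in set(gene_rows.columns)]
    if len(samples) < 3:
        raise ValueError("need at least 3 shared samples")
    gene_symbols = gene_symbols or {}
    if pairs is None:
        pairs = [(n, g) for n in ncrna_rows.index for g in gene_rows.index]
    hits: List[CorrelationHit] = []
    skipped: List[Tuple[str, str, str]] = []
    for ncrna_id, gene_id in pairs:
        x = ncrna_rows.loc[ncrna_id, samples].to_numpy(dtype=float)
        y = gene_rows.loc[gene_id, samples].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            skipped.append((str(ncrna_id), str(gene_id), "zero variance"))
            continue
        r, p = _pearson(x, y)
        if abs(r) >= r_min and p < p_max:
            hits.append(
                CorrelationHit(
                    str(ncrna_id),
                    str(gene_id),
                    str(gene_symbols.get(gene_id, "")),
                    r,
                    p,
                )
            )
    return hits, skipped
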