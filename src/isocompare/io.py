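"""Readers and writers for the file formats the pipeline consumes.

Conventions:

* GTF is 1-based closed; BED/BED12/bedGraph are 0-based half-open.  Internally
  everything is 0-based half-open, so conversion happens here and only here.
* BED12 ``name`` fields are written as ``gene_id|transcript_id`` so that the
  gene grouping round-trips; a bare name is read back with
  ``gene_id == transcript_id``.
* Unstranded records (strand ``.``) are rejected: splice-site semantics and
  sequence extraction need a strand.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple, Union

import pandas as pd

from .model import (
    ExpressionRecord,
    GeneCatalog,
    GenomicInterval,
    TranscriptModel,
    clean_sequence,
)

__all__ = [
    "AnnotationParseError",
    "read_annotation",
    "read_gtf",
    "read_bed12",
    "write_bed12",
    "write_gtf",
    "read_fasta",
    "write_fasta",
    "read_expression_table",
    "write_expression_table",
    "read_coding_scores",
    "read_bed_elements",
    "read_bedgraph",
    "read_wiggle",
    "read_probe_table",
    "read_expression_matrix",
]

PathLike = Union[str, Path]


class AnnotationParseError(ValueError):
    """Malformed annotation input; carries the offending line number."""

    def __init__(self, path: PathLike, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_annotation(path: PathLike, format: Optional[str] = None) -> GeneCatalog:
    """Read a gene annotation in GTF or BED12 format into a :class:`GeneCatalog`.

    ``format`` may be ``"GTF"`` or ``"BED12"``; if omitted it is inferred from
    the file extension (``.gtf`` vs ``.bed``).
    """
    if format is None:
        suffix = Path(path).suffix.lower()
        format = "GTF" if suffix in (".gtf", ".gff") else "BED12"
    fmt = format.upper()
    if fmt == "GTF":
        return read_gtf(path)
    if fmt == "BED12":
        return read_bed12(path)
    raise ValueError(f"unknown annotation format {format!r}")


def read_gtf(path: PathLike) -> GeneCatalog:
    """Parse exon features of a GTF file, converting to 0-based half-open."""
    exons: Dict[str, List[Tuple[int, int]]] = {}
    meta: Dict[str, Tuple[str, str, str]] = {}  # tid -> (gene_id, chrom, strand)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationParseError(
                    path, lineno, f"expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise AnnotationParseError(path, lineno, "non-integer coordinates")
            if start1 < 1 or end1 < start1:
                raise AnnotationParseError(
                    path, lineno, f"invalid GTF coordinates {start1}-{end1}"
                )
            if strand == ".":
                raise AnnotationParseError(
                    path, lineno, "unstranded exon (strand '.') is not supported"
                )
            if strand not in ("+", "-"):
                raise AnnotationParseError(path, lineno, f"bad strand {strand!r}")
            attr = dict(_GTF_ATTR_RE.findall(attrs))
            if "transcript_id" not in attr or "gene_id" not in attr:
                raise AnnotationParseError(
                    path, lineno, "exon line missing gene_id/transcript_id attributes"
                )
            tid, gid = attr["transcript_id"], attr["gene_id"]
            prev = meta.get(tid)
            if prev is not None and prev != (gid, chrom, strand):
                raise AnnotationParseError(
                    path, lineno, f"transcript {tid!r}: inconsistent gene/chrom/strand"
                )
            meta[tid] = (gid, chrom, strand)
            # GTF 1-based closed -> 0-based half-open
            exons.setdefault(tid, []).append((start1 - 1, end1))
    catalog = GeneCatalog()
    for tid, (gid, chrom, strand) in meta.items():
        ivs = tuple(
            GenomicInterval(chrom, s, e) for s, e in sorted(exons[tid])
        )
        catalog.add(TranscriptModel(tid, gid, chrom, strand, ivs))
    return catalog


def _split_bed_name(name: str) -> Tuple[str, str]:
    if "|" in name:
        gid, tid = name.split("|", 1)
        return gid, tid
    return name, name


def read_bed12(path: PathLike) -> GeneCatalog:
    """Parse BED12, expanding block fields into exons."""
    catalog = GeneCatalog()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise AnnotationParseError(
                    path, lineno, f"expected >=12 BED12 fields, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                chrom_start = int(fields[1])
                block_count = int(fields[9])
                block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                block_starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError:
                raise AnnotationParseError(path, lineno, "non-integer BED12 field")
            strand = fields[5]
            if strand == ".":
                raise AnnotationParseError(
                    path, lineno, "unstranded record (strand '.') is not supported"
                )
            if strand not in ("+", "-"):
                raise AnnotationParseError(path, lineno, f"bad strand {strand!r}")
            if len(block_sizes) != block_count or len(block_starts) != block_count:
                raise AnnotationParseError(
                    path, lineno, "blockCount does not match blockSizes/blockStarts"
                )
            if block_count == 0:
                raise AnnotationParseError(path, lineno, "record with zero blocks")
            gid, tid = _split_bed_name(fields[3])
            exons = tuple(
                GenomicInterval(chrom, chrom_start + off, chrom_start + off + size)
                for off, size in zip(block_starts, block_sizes)
            )
            try:
                catalog.add(TranscriptModel(tid, gid, chrom, strand, exons))
            except ValueError as exc:
                raise AnnotationParseError(path, lineno, str(exc))
    return catalog


def write_bed12(transcripts: Iterable[TranscriptModel], path: PathLike) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            span = t.span
            sizes = ",".join(str(len(ex)) for ex in t.exons)
            starts = ",".join(str(ex.start - span.start) for ex in t.exons)
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        str(span.start),
                        str(span.end),
                        f"{t.gene_id}|{t.transcript_id}",
                        "0",
                        t.strand,
                        str(span.start),
                        str(span.end),
                        "0",
                        str(t.num_exons),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def write_gtf(transcripts: Iterable[TranscriptModel], path: PathLike) -> None:
    """Write exon lines in GTF (1-based closed) with gene_id/transcript_id."""
    with open(path, "w") as fh:
        for t in transcripts:
            for ex in t.exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            "isocompare",
                            "exon",
                            str(ex.start + 1),
                            str(ex.end),
                            ".",
                            t.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_fasta(path: PathLike) -> Dict[str, str]:
    """Load a (small) FASTA into memory as {name: uppercase sequence}."""
    try:
        from pyfaidx import Fasta
    except ImportError:  # pragma: no cover
        Fasta = None
    if Fasta is not None:
        fa = Fasta(str(path))
        try:
            return {name: clean_sequence(str(fa[name][:])) for name in fa.keys()}
        finally:
            fa.close()
    # minimal fallback
    genome: Dict[str, List[str]] = {}
    name = None
    with open(path) as fh:  # pragma: no cover
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                genome[name] = []
            elif name is not None:
                genome[name].append(line)
    return {k: clean_sequence("".join(v)) for k, v in genome.items()}  # pragma: no cover


def write_fasta(seqs: Mapping[str, str], path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_expression_table(path: PathLike) -> List[ExpressionRecord]:
    """TSV with columns transcript_id and at least one of read_count / rpkm.

    Rows carrying only counts are returned with ``rpkm=0.0``; RPKM is then
    filled in (and reconciled against any supplied value) by
    :func:`isocompare.quantify.resolve_expression`.
    """
    df = pd.read_csv(path, sep="\t")
    if "transcript_id" not in df.columns:
        raise ValueError(f"{path}: missing transcript_id column")
    has_rpkm = "rpkm" in df.columns
    has_count = "read_count" in df.columns
    if not has_rpkm and not has_count:
        raise ValueError(f"{path}: need a read_count or rpkm column")
    records: List[ExpressionRecord] = []
    for row in df.itertuples(index=False):
        count = (
            None
            if not has_count or pd.isna(row.read_count)
            else int(row.read_count)
        )
        rpkm = float(row.rpkm) if has_rpkm else 0.0
        records.append(
            ExpressionRecord(str(row.transcript_id), rpkm=rpkm, read_count=count)
        )
    return records


def write_expression_table(records: Iterable[ExpressionRecord], path: PathLike) -> None:
    rows = [
        {
            "transcript_id": r.transcript_id,
            "read_count": "" if r.read_count is None else r.read_count,
            "rpkm": f"{r.rpkm:.6g}",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_coding_scores(path: PathLike) -> Dict[str, float]:
    """TSV with columns transcript_id, cpc_score -> {transcript_id: score}."""
    df = pd.read_csv(path, sep="\t")
    for col in ("transcript_id", "cpc_score"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing {col} column")
    return dict(zip(df["transcript_id"].astype(str), df["cpc_score"].astype(float)))


def read_bed_elements(path: PathLike) -> List[GenomicInterval]:
    """BED3+ intervals (e.g. phastCons conserved elements)."""
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise AnnotationParseError(path, lineno, "expected >=3 BED fields")
            try:
                out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise AnnotationParseError(path, lineno, str(exc))
    return out


def read_bedgraph(path: PathLike) -> Dict[str, List[Tuple[int, int, float]]]:
    """bedGraph -> {chrom: sorted [(start, end, score), ...]} (0-based half-open)."""
    runs: Dict[str, List[Tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise AnnotationParseError(path, lineno, "expected 4 bedGraph fields")
            try:
                chrom, start, end, score = (
                    fields[0],
                    int(fields[1]),
                    int(fields[2]),
                    float(fields[3]),
                )
            except ValueError:
                raise AnnotationParseError(path, lineno, "malformed bedGraph line")
            runs.setdefault(chrom, []).append((start, end, score))
    for chrom in runs:
        runs[chrom].sort()
    return runs


def read_wiggle(path: PathLike) -> Dict[str, List[Tuple[int, int, float]]]:
    """fixedStep / variableStep wiggle -> score runs, 0-based half-open.

    Wiggle positions are 1-based; each value covers ``span`` bases
    (default 1).
    """
    runs: Dict[str, List[Tuple[int, int, float]]] = {}
    mode = None
    chrom = ""
    pos = 0
    step = 1
    span = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep") or line.startswith("variableStep"):
                kv = dict(
                    part.split("=", 1) for part in line.split()[1:] if "=" in part
                )
                if "chrom" not in kv:
                    raise AnnotationParseError(path, lineno, "wiggle header missing chrom")
                chrom = kv["chrom"]
                span = int(kv.get("span", 1))
                if line.startswith("fixedStep"):
                    mode = "fixed"
                    pos = int(kv["start"]) - 1
                    step = int(kv.get("step", 1))
                else:
                    mode = "variable"
                continue
            if mode is None:
                raise AnnotationParseError(path, lineno, "wiggle data before header")
            if mode == "fixed":
                score = float(line)
                runs.setdefault(chrom, []).append((pos, pos + span, score))
                pos += step
            else:
                parts = line.split()
                if len(parts) != 2:
                    raise AnnotationParseError(path, lineno, "bad variableStep line")
                p = int(parts[0]) - 1
                runs.setdefault(chrom, []).append((p, p + span, float(parts[1])))
    for c in runs:
        runs[c].sort()
    return runs


def read_score_track(path: PathLike) -> Dict[str, List[Tuple[int, int, float]]]:
    """Dispatch a base-score track by extension: bedGraph, wiggle or bigWig.

    bigWig support needs pyBigWig (optional); intervals are read per
    chromosome into (start, end, score) runs.
    """
    suffix = Path(path).suffix.lower()
    if suffix in (".bw", ".bigwig"):
        import pyBigWig  # optional dependency

        runs: Dict[str, List[Tuple[int, int, float]]] = {}
        bw = pyBigWig.open(str(path))
        try:
            for chrom in bw.chroms():
                ivs = bw.intervals(chrom) or []
                runs[chrom] = [(s, e, float(v)) for s, e, v in ivs]
        finally:
            bw.close()
        return runs
    if suffix in (".wig", ".wiggle"):
        return read_wiggle(path)
    return read_bedgraph(path)


def read_probe_table(path: PathLike) -> pd.DataFrame:
    """Probe TSV with columns probe_id, sequence and optional gene_symbol."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("probe_id", "sequence"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing {col} column")
    df["sequence"] = df["sequence"].map(clean_sequence)
    if "gene_symbol" not in df.columns:
        df["gene_symbol"] = ""
    df["gene_symbol"] = df["gene_symbol"].fillna("")
    return df


def read_expression_matrix(path: PathLike) -> pd.DataFrame:
    """Probes x samples matrix; first column is probe_id, remaining samples."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    return df.astype(float)
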