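"""Stage orchestration: configuration, fail-fast validation, reports.

Each stage reads the formats defined in :mod:`isocompare.io`, calls the
library, and writes TSV/JSON outputs plus a manifest recording inputs,
thresholds and the seed.  Re-running with the same config and inputs is
bit-identical for the deterministic stages.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import io as iio
from .coding import classify_sample
from .compare import summarize_comparison
from .conservation import ConservationTrack, clade_conservation_summary
from .model import SampleTranscriptome, extract_transcript_sequence
from .quantify import LibrarySize, filter_expressed, resolve_expression
from .screen import Probe, correlation_screen, differential_expression, match_probes
from .splice import tally_splice_classes

__all__ = ["PipelineConfig", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("quantify", "classify", "compare", "splice", "conserve", "screen")


@dataclass
class PipelineConfig:
    """All inputs and thresholds of a pipeline run.

    Thresholds default to the values the comparison was designed around:
    expressed at >=0.1 RPKM, long ncRNA at >200 nt, coding at score >0,
    conserved base at score >=0.9, correlation hit at |r|>=0.4 and p<0.05,
    DE at Benjamini-Hochberg q<0.05.
    """

    out_dir: str = "results/pipeline"
    # reference annotation & genome
    annotation: Optional[str] = None
    genome: Optional[str] = None
    # per-sample inferred transcript models (BED12); default to the annotation
    transcripts_a: Optional[str] = None
    transcripts_b: Optional[str] = None
    # per-sample expression + coding scores
    sample_a: str = "brain"
    sample_b: str = "cell_lines"
    expression_a: Optional[str] = None
    expression_b: Optional[str] = None
    library_size_a: Optional[int] = None
    library_size_b: Optional[int] = None
    scores_a: Optional[str] = None
    scores_b: Optional[str] = None
    # conservation inputs: clade -> path
    elements: Dict[str, str] = field(default_factory=dict)
    scores_tracks: Dict[str, str] = field(default_factory=dict)
    # disease screen inputs
    probes: Optional[str] = None
    ncrna_matrix: Optional[str] = None
    gene_matrix: Optional[str] = None
    case_samples: List[str] = field(default_factory=list)
    control_samples: List[str] = field(default_factory=list)
    # thresholds
    min_rpkm: float = 0.1
    lncrna_min_len: int = 201
    coding_cutoff: float = 0.0
    cons_cutoff: float = 0.9
    r_min: float = 0.4
    p_max: float = 0.05
    fdr: float = 0.05
    identity: str = "exon_chain"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cons_cutoff <= 1.0:
            raise ValueError("cons_cutoff must be in [0,1]")
        if self.min_rpkm < 0 or self.fdr <= 0 or self.fdr >= 1:
            raise ValueError("min_rpkm must be >=0 and fdr in (0,1)")
        if not 0.0 <= self.r_min <= 1.0 or not 0.0 < self.p_max <= 1.0:
            raise ValueError("r_min in [0,1] and p_max in (0,1] required")
        if self.lncrna_min_len < 1:
            raise ValueError("lncrna_min_len must be >=1")

    @classmethod
    def from_toml(cls, path: str, **overrides) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


_REQUIRED = {
    "quantify": ("annotation", "expression_a", "expression_b"),
    "classify": ("annotation", "expression_a", "expression_b", "scores_a", "scores_b"),
    "compare": ("annotation", "expression_a", "expression_b"),
    "splice": ("annotation", "expression_a", "expression_b", "scores_a", "scores_b"),
    "conserve": ("annotation", "expression_a", "expression_b", "scores_a", "scores_b"),
    "screen": ("probes", "ncrna_matrix", "gene_matrix", "annotation", "genome"),
}


def _validate(config: PipelineConfig, stages: Sequence[str]) -> None:
    problems: List[str] = []
    for stage in stages:
        if stage not in ALL_STAGES:
            problems.append(f"unknown stage {stage!r}")
            continue
        for attr in _REQUIRED[stage]:
            value = getattr(config, attr)
            if not value:
                problems.append(f"stage {stage}: missing input {attr!r}")
            elif isinstance(value, str) and not Path(value).exists():
                problems.append(f"stage {stage}: input file not found: {value}")
        if stage == "conserve" and not (config.elements or config.scores_tracks):
            problems.append("stage conserve: need elements and/or scores_tracks")
        if stage == "screen" and (
            len(config.case_samples) < 2 or len(config.control_samples) < 2
        ):
            problems.append("stage screen: need >=2 case and >=2 control samples")
    if problems:
        raise ValueError("pipeline pre-flight failed:\n  " + "\n  ".join(problems))


def _load_sample(
    config: PipelineConfig, which: str
) -> Tuple[SampleTranscriptome, dict]:
    tx_path = getattr(config, f"transcripts_{which}") or config.annotation
    catalog = iio.read_annotation(tx_path)
    records = iio.read_expression_table(getattr(config, f"expression_{which}"))
    lib_n = getattr(config, f"library_size_{which}")
    library = LibrarySize(lib_n) if lib_n else None
    by_tid = {t.transcript_id: t for t in catalog}
    records = resolve_expression(records, by_tid, library)
    pairs = [(by_tid[r.transcript_id], r) for r in records]
    sample, report = filter_expressed(
        pairs, config.min_rpkm, getattr(config, f"sample_{which}")
    )
    return sample, {
        "input_records": len(records),
        "retained": report.retained,
        "dropped": report.dropped,
        "threshold": report.threshold,
    }


def run_pipeline(config: PipelineConfig, stages: Sequence[str] = ALL_STAGES) -> dict:
    """Run the selected stages; fail fast if any required input is missing.

    Returns the manifest (also written to ``<out_dir>/manifest.json``).
    """
    stages = list(stages)
    _validate(config, stages)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: v for k, v in asdict(config).items()},
        "stages": {},
    }

    needs_samples = any(s in stages for s in ("quantify", "classify", "compare", "splice", "conserve"))
    sample_a = sample_b = None
    if needs_samples:
        sample_a, stats_a = _load_sample(config, "a")
        sample_b, stats_b = _load_sample(config, "b")

    assessments_a = assessments_b = categories_a = categories_b = None
    if any(s in stages for s in ("classify", "splice", "conserve")) or (
        "compare" in stages and config.scores_a and config.scores_b
    ):
        if config.scores_a and config.scores_b:
            scores_a = iio.read_coding_scores(config.scores_a)
            scores_b = iio.read_coding_scores(config.scores_b)
            assessments_a, categories_a = classify_sample(
                sample_a, scores_a, config.coding_cutoff
            )
            assessments_b, categories_b = classify_sample(
                sample_b, scores_b, config.coding_cutoff
            )

    if "quantify" in stages:
        for sample, stats in ((sample_a, stats_a), (sample_b, stats_b)):
            iio.write_bed12(
                sorted(sample.transcripts(), key=lambda t: t.transcript_id),
                out / f"{sample.sample_name}.expressed.bed12",
            )
            iio.write_expression_table(
                sorted(
                    (rec for _, rec in sample.records.values()),
                    key=lambda r: r.transcript_id,
                ),
                out / f"{sample.sample_name}.expressed.tsv",
            )
        manifest["stages"]["quantify"] = {"a": stats_a, "b": stats_b}

    if "classify" in stages:
        for name, assessments, categories in (
            (config.sample_a, assessments_a, categories_a),
            (config.sample_b, assessments_b, categories_b),
        ):
            rows = [
                {
                    "transcript_id": a.transcript_id,
                    "gene_id": a.gene_id,
                    "cpc_score": a.score,
                    "label": a.label.value,
                }
                for a in sorted(assessments.values(), key=lambda a: a.transcript_id)
            ]
            pd.DataFrame(rows).to_csv(out / f"{name}.labels.tsv", sep="\t", index=False)
            crows = [
                {"gene_id": c.gene_id, "category": c.category.value}
                for c in sorted(categories.values(), key=lambda c: c.gene_id)
            ]
            pd.DataFrame(crows).to_csv(
                out / f"{name}.gene_categories.tsv", sep="\t", index=False
            )
        counts = {
            name: pd.Series([a.label.value for a in assessments.values()])
            .value_counts()
            .to_dict()
            for name, assessments in (
                (config.sample_a, assessments_a),
                (config.sample_b, assessments_b),
            )
        }
        manifest["stages"]["classify"] = counts

    if "compare" in stages:
        summary = summarize_comparison(
            sample_a,
            sample_b,
            config.identity,
            assessments_a,
            assessments_b,
            categories_a,
            categories_b,
        )
        with open(out / "comparison.json", "w") as fh:
            json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
        manifest["stages"]["compare"] = summary.to_dict()

    if "splice" in stages:
        catalog = iio.read_annotation(config.annotation)
        from .coding import TranscriptClass

        lnc_a = [
            sample_a.records[a.transcript_id][0]
            for a in assessments_a.values()
            if a.label == TranscriptClass.LONG_NCRNA
        ]
        lnc_b = [
            sample_b.records[a.transcript_id][0]
            for a in assessments_b.values()
            if a.label == TranscriptClass.LONG_NCRNA
        ]
        stage_out = {}
        for name, lncs in ((config.sample_a, lnc_a), (config.sample_b, lnc_b)):
            tally = tally_splice_classes(lncs, catalog)
            rows = []
            for t in sorted(lncs, key=lambda t: t.transcript_id):
                from .splice import classify_splice_structure

                cls = classify_splice_structure(t, catalog.transcripts_of(t.gene_id))
                rows.append({"transcript_id": t.transcript_id, "splice_class": cls.value})
            pd.DataFrame(rows, columns=["transcript_id", "splice_class"]).to_csv(
                out / f"{name}.splice_classes.tsv", sep="\t", index=False
            )
            stage_out[name] = {c.value: n for c, n in tally.counts.items()}
            stage_out[name]["excluded_unannotated"] = len(tally.excluded)
        manifest["stages"]["splice"] = stage_out

    if "conserve" in stages:
        from .coding import TranscriptClass

        lncs = sorted(
            {
                a.transcript_id: sample.records[a.transcript_id][0]
                for sample, assessments in (
                    (sample_a, assessments_a),
                    (sample_b, assessments_b),
                )
                for a in assessments.values()
                if a.label == TranscriptClass.LONG_NCRNA
            }.values(),
            key=lambda t: t.transcript_id,
        )
        tracks = []
        clades = sorted(set(config.elements) | set(config.scores_tracks))
        for clade in clades:
            elements = (
                iio.read_bed_elements(config.elements[clade])
                if clade in config.elements
                else []
            )
            runs = (
                iio.read_score_track(config.scores_tracks[clade])
                if clade in config.scores_tracks
                else {}
            )
            tracks.append(ConservationTrack(clade, runs, elements))
        rows, aggregate = clade_conservation_summary(lncs, tracks, config.cons_cutoff)
        pd.DataFrame(
            [
                {
                    "transcript_id": r.transcript_id,
                    "clade": r.clade,
                    "base_conserved_fraction": round(r.base_conserved_fraction, 6),
                    "element_overlap_ratio": round(r.element_overlap_ratio, 6),
                    "contains_element": r.contains_element,
                }
                for r in rows
            ]
        ).to_csv(out / "conservation.tsv", sep="\t", index=False)
        manifest["stages"]["conserve"] = {
            "aggregate_contains_element": aggregate,
            "n_long_ncrnas": len(lncs),
        }

    if "screen" in stages:
        if config.transcripts_a or config.transcripts_b:
            merged: Dict[str, object] = {}
            for path in (config.transcripts_a, config.transcripts_b):
                if path:
                    for t in iio.read_annotation(path):
                        merged[t.transcript_id] = t
            target_transcripts = list(merged.values())
        else:
            target_transcripts = list(iio.read_annotation(config.annotation))
        genome = iio.read_fasta(config.genome)
        probe_df = iio.read_probe_table(config.probes)
        probes = [
            Probe(r.probe_id, r.sequence, r.gene_symbol)
            for r in probe_df.itertuples(index=False)
        ]
        with_seqs = [
            (t, extract_transcript_sequence(genome, t)) for t in target_transcripts
        ]
        matches, rejected = match_probes(probes, with_seqs)
        pd.DataFrame(
            [
                {
                    "probe_id": m.probe_id,
                    "transcript_id": m.transcript_id,
                    "offset": m.offset,
                }
                for m in sorted(matches, key=lambda m: m.probe_id)
            ],
            columns=["probe_id", "transcript_id", "offset"],
        ).to_csv(out / "probe_matches.tsv", sep="\t", index=False)

        ncrna = iio.read_expression_matrix(config.ncrna_matrix)
        genes = iio.read_expression_matrix(config.gene_matrix)
        de = differential_expression(
            ncrna, config.case_samples, config.control_samples, config.fdr
        )
        pd.DataFrame(
            [
                {
                    "probe_id": r.probe_id,
                    "log2_mean_diff": round(r.log2_mean_diff, 6),
                    "p_value": r.p_value,
                    "q_value": r.q_value,
                    "differential": r.differential,
                }
                for r in de
            ]
        ).to_csv(out / "differential_expression.tsv", sep="\t", index=False)
        de_probes = [r.probe_id for r in de if r.differential]
        import numpy as np

        log_nc = np.log2(ncrna + 1.0)
        log_g = np.log2(genes + 1.0)
        hits, skipped = correlation_screen(
            log_nc.loc[de_probes] if de_probes else log_nc.iloc[:0],
            log_g,
            r_min=config.r_min,
            p_max=config.p_max,
        )
        pd.DataFrame(
            [
                {
                    "ncrna_probe_id": h.ncrna_probe_id,
                    "gene_probe_id": h.gene_probe_id,
                    "gene_symbol": h.gene_symbol,
                    "r": round(h.r, 6),
                    "p_value": h.p_value,
                }
                for h in hits
            ],
            columns=["ncrna_probe_id", "gene_probe_id", "gene_symbol", "r", "p_value"],
        ).to_csv(out / "correlation_hits.tsv", sep="\t", index=False)
        manifest["stages"]["screen"] = {
            "probes_matched": len(matches),
            "probes_rejected": len(rejected),
            "de_probes": len(de_probes),
            "correlation_hits": len(hits),
            "correlation_skipped": len(skipped),
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
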