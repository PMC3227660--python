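"""Write a complete synthetic input bundle in the formats the pipeline reads.

The bundle is a directory of plain-text files — GTF annotation, FASTA genome,
expression and coding-score TSVs for both samples (including sub-threshold
records so the expressed filter has something to drop), per-clade conserved
element BED and base-score bedGraph, a probe table, case/control expression
matrices — plus a ready-to-run ``config.toml`` and the ground truth as JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as iio
from .coding import TranscriptClass, classify_transcript
from .model import (
    GeneCatalog,
    SampleTranscriptome,
    TranscriptModel,
    extract_transcript_sequence,
)
from .pipeline import PipelineConfig
from .simulate import (
    GroundTruth,
    generate_conservation_tracks,
    generate_disease_matrices,
    generate_gene_catalog,
    generate_paired_transcriptomes,
    subthreshold_records,
)

__all__ = ["generate_bundle"]


def _make_probes(
    lncs: List[Tuple[TranscriptModel, str]],
    all_seqs: List[str],
    rng: np.random.Generator,
    n_unique: int = 20,
    probe_len: int = 25,
) -> pd.DataFrame:
    """Probes that match one long ncRNA each, plus no-match and multi-match
    controls; uniqueness verified against every supplied sequence."""

    def occurrences(needle: str) -> int:
        total = 0
        for seq in all_seqs:
            start = 0
            while True:
                i = seq.find(needle, start)
                if i < 0:
                    break
                total += 1
                start = i + 1
        return total

    rows = []
    used = set()
    for t, seq in lncs:
        if len(rows) >= n_unique or len(seq) < probe_len:
            continue
        for _ in range(30):
            off = int(rng.integers(0, len(seq) - probe_len + 1))
            cand = seq[off : off + probe_len]
            if cand not in used and occurrences(cand) == 1:
                used.add(cand)
                rows.append(
                    {"probe_id": f"probe{len(rows) + 1:03d}", "sequence": cand,
                     "gene_symbol": ""}
                )
                break
    # no-match controls: random sequences re-drawn until absent everywhere
    for j in range(3):
        for _ in range(50):
            cand = "".join(np.array(list("ACGT"))[rng.integers(0, 4, probe_len)])
            if occurrences(cand) == 0:
                rows.append(
                    {"probe_id": f"nomatch{j + 1}", "sequence": cand, "gene_symbol": ""}
                )
                break
    # multi-match control: a substring occurring in >=2 sequences if one exists
    for t, seq in lncs:
        cand = seq[: probe_len]
        if len(cand) == probe_len and occurrences(cand) > 1:
            rows.append(
                {"probe_id": "multimatch1", "sequence": cand, "gene_symbol": ""}
            )
            break
    return pd.DataFrame(rows, columns=["probe_id", "sequence", "gene_symbol"])


def generate_bundle(
    out_dir: str,
    seed: int = 0,
    n_genes: int = 120,
    n_bifunctional: Tuple[int, int, int] = (4, 5, 2),
    switch_counts: Tuple[int, int, int, int] = (3, 3, 2, 2),
    n_splice_variants: Tuple[int, int, int] = (2, 3, 3),
    coverage_frac: float = 0.8,
    n_probes: int = 120,
    n_case: int = 12,
    n_control: int = 12,
) -> Tuple[PipelineConfig, GroundTruth]:
    """Generate every pipeline input under ``out_dir`` and return the config
    pointing at the files plus the recorded ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed + 1)

    catalog, genome = generate_gene_catalog(n_genes, seed=seed)
    A, B, truth = generate_paired_transcriptomes(
        catalog,
        n_bifunctional=n_bifunctional,
        switch_counts=switch_counts,
        n_splice_variants=n_splice_variants,
        seed=seed,
    )
    iio.write_gtf(list(catalog), out / "annotation.gtf")
    iio.write_fasta(genome, out / "genome.fa")

    for sample, tag in ((A, "a"), (B, "b")):
        recs = [rec for _, rec in sample.records.values()]
        recs += subthreshold_records(catalog, sample, seed=seed)
        recs.sort(key=lambda r: r.transcript_id)
        iio.write_expression_table(recs, out / f"expression_{tag}.tsv")
        # inferred transcript models of this sample: the annotation plus any
        # novel transcripts only this quantification produced
        models = {t.transcript_id: t for t in catalog}
        models.update({t.transcript_id: t for t in sample.transcripts()})
        iio.write_bed12(
            [models[tid] for tid in sorted(models)],
            out / f"transcripts_{tag}.bed12",
        )
        score_rows = [
            {
                "transcript_id": tid,
                "cpc_score": round(truth.coding_scores[tid], 4),
            }
            for tid in sorted(
                {t.transcript_id for t in sample.transcripts()}
            )
        ]
        pd.DataFrame(score_rows).to_csv(
            out / f"scores_{tag}.tsv", sep="\t", index=False
        )

    # conservation over the union of expressed long ncRNAs
    lnc_ts = sorted(
        {
            t.transcript_id: t
            for sample in (A, B)
            for t in sample.transcripts()
            if not truth.coding_label[t.transcript_id]
            and t.spliced_length > 200
        }.values(),
        key=lambda t: t.transcript_id,
    )
    tracks, cons_truth = generate_conservation_tracks(
        lnc_ts, coverage_frac=coverage_frac, seed=seed
    )
    truth.covered_transcripts = cons_truth.covered_transcripts
    truth.clade_coverage = cons_truth.clade_coverage
    truth.element_fraction = cons_truth.element_fraction
    elements_paths: Dict[str, str] = {}
    scores_paths: Dict[str, str] = {}
    for track in tracks:
        bed = out / f"elements.{track.clade}.bed"
        with open(bed, "w") as fh:
            for el in sorted(track.elements, key=lambda e: (e.chrom, e.start)):
                fh.write(f"{el.chrom}\t{el.start}\t{el.end}\n")
        bg = out / f"scores.{track.clade}.bedgraph"
        with open(bg, "w") as fh:
            for chrom in sorted(track.score_runs):
                for s, e, score in track.score_runs[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\t{score}\n")
        elements_paths[track.clade] = str(bed)
        scores_paths[track.clade] = str(bg)

    # probes against the spliced sequences of the expressed transcripts
    all_with_seqs = [
        (t, extract_transcript_sequence(genome, t))
        for t in sorted(
            {t.transcript_id: t for s in (A, B) for t in s.transcripts()}.values(),
            key=lambda t: t.transcript_id,
        )
    ]
    lnc_with_seqs = [(t, s) for t, s in all_with_seqs if t in set(lnc_ts)]
    probe_df = _make_probes(lnc_with_seqs, [s for _, s in all_with_seqs], rng)
    probe_df.to_csv(out / "probes.tsv", sep="\t", index=False)

    ncrna, genes, cases, controls, dis_truth = generate_disease_matrices(
        n_probes=n_probes, n_case=n_case, n_control=n_control, seed=seed,
        corr_on_de=True,
    )
    truth.de_probes = dis_truth.de_probes
    truth.effect_size = dis_truth.effect_size
    truth.corr_pairs = dis_truth.corr_pairs
    truth.rho = dis_truth.rho
    ncrna.round(4).to_csv(out / "ncrna_matrix.tsv", sep="\t")
    genes.round(4).to_csv(out / "gene_matrix.tsv", sep="\t")

    config = PipelineConfig(
        out_dir=str(out / "pipeline"),
        annotation=str(out / "annotation.gtf"),
        genome=str(out / "genome.fa"),
        transcripts_a=str(out / "transcripts_a.bed12"),
        transcripts_b=str(out / "transcripts_b.bed12"),
        expression_a=str(out / "expression_a.tsv"),
        expression_b=str(out / "expression_b.tsv"),
        scores_a=str(out / "scores_a.tsv"),
        scores_b=str(out / "scores_b.tsv"),
        elements=elements_paths,
        scores_tracks=scores_paths,
        probes=str(out / "probes.tsv"),
        ncrna_matrix=str(out / "ncrna_matrix.tsv"),
        gene_matrix=str(out / "gene_matrix.tsv"),
        case_samples=cases,
        control_samples=controls,
        seed=seed,
    )
    _write_config_toml(config, out / "config.toml")
    with open(out / "truth.json", "w") as fh:
        json.dump(_truth_to_json(truth), fh, indent=2, sort_keys=True)
    return config, truth


def _write_config_toml(config: PipelineConfig, path: Path) -> None:
    def fmt(v) -> str:
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, (int, float)):
            return repr(v)
        if isinstance(v, str):
            return json.dumps(v)
        if isinstance(v, list):
            return "[" + ", ".join(fmt(x) for x in v) + "]"
        raise TypeError(type(v))

    lines: List[str] = []
    tables: List[str] = []
    for key, value in asdict(config).items():
        if value is None:
            continue
        if isinstance(value, dict):
            if value:
                tables.append(f"[{key}]")
                tables.extend(f"{k} = {fmt(v)}" for k, v in value.items())
                tables.append("")
        else:
            lines.append(f"{key} = {fmt(value)}")
    path.write_text("\n".join(lines + [""] + tables))


def _truth_to_json(truth: GroundTruth) -> dict:
    d = asdict(truth)
    out = {}
    for k, v in d.items():
        if isinstance(v, set):
            out[k] = sorted(v)
        elif isinstance(v, dict):
            out[k] = {
                (k2 if isinstance(k2, str) else "|".join(map(str, k2))): (
                    sorted(v2) if isinstance(v2, set) else
                    v2.value if hasattr(v2, "value") else v2
                )
                for k2, v2 in v.items()
            }
        elif isinstance(v, list):
            out[k] = [list(x) if isinstance(x, tuple) else x for x in v]
        else:
            out[k] = v
    return out
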