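"""Compare the two samples at gene versus isoform resolution.

The headline phenomenon: most expressed genes are shared between the samples
while most expressed isoforms are not — common genes express different exon
chains.  Also reports identical-isoform-set genes, category-switch genes and
the bifunctional-gene union.
"""

from __future__ import annotations

import json
import shutil
from pathlib import Path

from isocompare.pipeline import PipelineConfig, run_pipeline

BUNDLE = Path("scratch/synthetic")
RESULTS = Path("results")


def main() -> None:
    config = PipelineConfig.from_toml(str(BUNDLE / "config.toml"))
    manifest = run_pipeline(config, ["quantify", "classify", "compare"])
    c = manifest["stages"]["compare"]
    n_a = c["genes_common"] + c["genes_a_only"]
    n_b = c["genes_common"] + c["genes_b_only"]
    i_a = c["isoforms_common"] + c["isoforms_a_only"]
    print(
        f"genes: {c['genes_common']} common of {n_a} (A) / {n_b} (B); "
        f"A-only {c['genes_pct_a_only']}%, B-only {c['genes_pct_b_only']}%"
    )
    print(
        f"isoforms: {c['isoforms_common']} common of {i_a} (A); "
        f"A-only {c['isoforms_pct_a_only']}%, B-only {c['isoforms_pct_b_only']}%"
    )
    print(
        f"identical-isoform-set genes: {c['identical_isoform_set_genes']} "
        f"of {c['genes_common']} common genes"
    )
    print(
        "category switches (lncRNA A-only / B-only, coding A-only / B-only): "
        f"{c['lncrna_a_only_genes']} / {c['lncrna_b_only_genes']}, "
        f"{c['coding_a_only_genes']} / {c['coding_b_only_genes']}"
    )
    print(
        f"bifunctional genes: union {c['bifunctional_union']} "
        f"({c['bifunctional_common']} in both samples)"
    )
    shutil.copy(Path(config.out_dir) / "comparison.json", RESULTS / "03_comparison.json")


if __name__ == "__main__":
    main()
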