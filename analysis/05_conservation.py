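"""Conservation of the expressed long ncRNAs: per-clade base-score fractions
(score >= 0.9) and conserved-element overlap ratios, plus the share of long
ncRNAs containing at least one conserved element per clade."""

from __future__ import annotations

import shutil
from pathlib import Path

from isocompare.pipeline import PipelineConfig, run_pipeline

BUNDLE = Path("scratch/synthetic")
RESULTS = Path("results")


def main() -> None:
    config = PipelineConfig.from_toml(str(BUNDLE / "config.toml"))
    manifest = run_pipeline(config, ["quantify", "classify", "conserve"])
    c = manifest["stages"]["conserve"]
    print(f"long ncRNAs examined: {c['n_long_ncrnas']}")
    for clade, frac in sorted(c["aggregate_contains_element"].items()):
        print(f"  {clade}: {frac:.3f} contain a conserved element")
    shutil.copy(Path(config.out_dir) / "conservation.tsv", RESULTS / "05_conservation.tsv")


if __name__ == "__main__":
    main()
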