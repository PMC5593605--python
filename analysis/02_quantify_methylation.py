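"""Tile methylation levels and the demethylation wave.

Quantifies 100-bp tile methylation per sample (pooling CpGs covered >= 5x),
averages biological replicates into stage methylomes, and summarizes the
global dynamics: mean tile methylation per stage and the low/intermediate/
high status fractions. The wave should be high in sperm, minimal at the
2-cell stage, and restored after implantation.
"""

import pandas as pd

from common import RESULTS, ensure_stage

run = ensure_stage("quant")
summary = pd.read_csv(run / "quant" / "sample_summary.tsv", sep="\t")

stage_order = summary["stage"].drop_duplicates().tolist()
per_stage = (
    summary.groupby("stage", sort=False)
    .agg(
        mean_level=("mean_level", "mean"),
        n_tiles=("n_tiles", "mean"),
        frac_low=("frac_low", "mean"),
        frac_intermediate=("frac_intermediate", "mean"),
        frac_high=("frac_high", "mean"),
    )
    .loc[stage_order]
    .round(4)
)
print("stage-level methylation (replicate means):")
print(per_stage.to_string())

nadir = per_stage["mean_level"].idxmin()
print(f"\ndemethylation wave bottoms at: {nadir}")

per_stage.to_csv(RESULTS / "02_stage_methylation.tsv", sep="\t")
print(f"table -> {RESULTS / '02_stage_methylation.tsv'}")
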