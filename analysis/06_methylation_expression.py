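"""Promoter and gene-body methylation versus expression, per stage.

Correlates per-gene regional methylation with log2(stage-mean FPKM + 1)
across genes, stage by stage. Under the planted regulatory model promoter
methylation represses (negative r at every stage) while gene-body
methylation tracks expression positively.
"""

import shutil

import pandas as pd

from common import RESULTS, ensure_stage

run = ensure_stage("correlate")
tables = {}
for region in ("promoter", "genebody"):
    t = pd.read_csv(run / "correlate" / f"correlation_{region}.tsv", sep="\t")
    tables[region] = t
    shutil.copy(
        run / "correlate" / f"correlation_{region}.tsv",
        RESULTS / f"06_correlation_{region}.tsv",
    )

merged = tables["promoter"][["stage", "r"]].merge(
    tables["genebody"][["stage", "r"]], on="stage", suffixes=("_promoter", "_genebody")
)
print("per-stage Pearson r (methylation vs log2 expression):")
print(merged.round(3).to_string(index=False))

neg = (merged["r_promoter"] < 0).mean()
print(f"\npromoter r negative in {neg:.0%} of stages "
      f"(mean r = {merged['r_promoter'].mean():.3f})")
print(f"gene-body mean r = {merged['r_genebody'].mean():.3f}")
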