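"""TSS meta-profiles: methylation and CpG density, lncRNA vs coding.

Bins tile methylation (sperm stage) and tile CpG density into 100-bp windows
5 kb around each TSS, strand-oriented, separately for distal lncRNAs
(>= 1 kb from any coding gene) and protein-coding genes, and compares the
promoter-level distributions between the classes with a two-sample K-S test.
Expected shape: a V-shaped dip at the TSS in both classes, with lncRNA
promoters less CpG-dense but more methylated.
"""

import json
import shutil

import pandas as pd

from common import RESULTS, ensure_stage

run = ensure_stage("profiles")

for tag in ("methylation", "cpg_density"):
    rows = {}
    for cls in ("lncRNA", "coding"):
        prof = pd.read_csv(run / "profiles" / f"tss_{tag}_{cls}.tsv", sep="\t")
        rows[cls] = prof.set_index("offset_bp")["mean"]
        shutil.copy(
            run / "profiles" / f"tss_{tag}_{cls}.tsv",
            RESULTS / f"03_tss_{tag}_{cls}.tsv",
        )
    both = pd.DataFrame(rows)
    center = both.loc[-200:100].mean()
    flank = pd.concat([both.loc[:-4000], both.loc[4000:]]).mean()
    print(f"{tag}: value at TSS vs distal flank")
    for cls in both.columns:
        print(f"  {cls:8s} TSS {center[cls]:.3f}  flank {flank[cls]:.3f}")

ks = json.loads((run / "profiles" / "ks_tests.json").read_text())
print("\nK-S comparisons (lncRNA vs coding):")
for name, res in ks.items():
    print(f"  {name}: D = {res['D']:.3f}, p = {res['p']:.3g}")
(RESULTS / "03_ks_tests.json").write_text(json.dumps(ks, indent=2))
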