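"""Generate the synthetic study fixture.

Emulates the shape of an RRBS developmental series (9 stages from gametes to
post-implantation, 2 replicates each) plus a single-cell FPKM matrix:
a demethylation wave bottoming at the 2-cell stage, planted sperm-/oocyte-
specific DMRs, planted stage-specific DMRs, CpG-poor but hotter lncRNA
promoters, negative promoter-methylation coupling, and co-expression
modules. Everything planted is recorded in ground-truth tables.
"""

import json

from common import RESULTS, SEED, ensure_stage

run = ensure_stage("simulate")
manifest = json.loads((run / "fixture" / "manifest.json").read_text())

print(f"fixture written to {run / 'fixture'} (seed {SEED})")
print(f"  genes:   {manifest['n_genes']}")
print(f"  CpGs:    {manifest['n_cpgs']}")
print(f"  samples: {manifest['n_samples']} (methylomes)")

(RESULTS / "01_fixture_summary.json").write_text(json.dumps(manifest, indent=2))
print(f"summary -> {RESULTS / '01_fixture_summary.json'}")
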