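"""Coding-noncoding co-expression network seeded by promoter D-DMR genes.

Filters genes (max FPKM > 5, variance in the top 75%), computes all-pairs
Pearson correlations with Fisher-asymptotic p-values over the single-cell
matrix, keeps pairs with |r| > 0.8 and p < 0.05 touching at least one gene
whose promoter holds a D-DMR, and reports topology, recovery of the planted
modules, and module enrichment among network members.
"""

import json
import shutil

import pandas as pd

from common import RESULTS, ensure_stage
from pedmeth import evaluate

run = ensure_stage("enrich")
edges = pd.read_csv(run / "network" / "edges.tsv", sep="\t")
nodes = pd.read_csv(run / "network" / "nodes.tsv", sep="\t")
topo = json.loads((run / "network" / "topology.json").read_text())
modules = pd.read_csv(run / "fixture" / "truth" / "modules.tsv", sep="\t")

print(f"network: {topo['n_lncrna']} lncRNA + {topo['n_coding']} coding nodes, "
      f"{topo['n_edges']} edges; components {topo['component_sizes']}")
print(f"hub genes (top degree): {', '.join(topo['hubs'][:5])}")

rec = evaluate.module_edge_precision(edges, modules)
print(f"planted-module edge precision: {rec['precision']:.2%} "
      f"({rec['n_within_module']}/{rec['n_edges']} edges within a planted module)")

enr = pd.read_csv(run / "enrich" / "enrichment.tsv", sep="\t")
if not enr.empty:
    print("\nmodule enrichment among network genes:")
    print(enr.round(4).to_string(index=False))
    shutil.copy(run / "enrich" / "enrichment.tsv", RESULTS / "07_enrichment.tsv")

shutil.copy(run / "network" / "edges.tsv", RESULTS / "07_edges.tsv")
shutil.copy(run / "network" / "nodes.tsv", RESULTS / "07_nodes.tsv")
(RESULTS / "07_topology.json").write_text(json.dumps(topo, indent=2))
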