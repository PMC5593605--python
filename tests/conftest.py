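"""Shared fixtures: one default synthetic dataset per session, plus the
derived tile/stage methylomes and an in-memory run of the main analyses."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import pedmeth as pm
from pedmeth import annotation as ann_mod
from pedmeth import ddmr as ddmr_mod
from pedmeth import gdmr as gdmr_mod
from pedmeth import network as net_mod
from pedmeth.expression import methylation_expression_correlation

DEFAULT_SEED = 0

#: compact configuration for tests that need their own fresh simulation
SMALL_CONFIG = dict(
    n_coding=30,
    n_lncrna=20,
    chrom_sizes={"chrA": 200_000, "chrB": 120_000},
    n_gdmr_sperm=5,
    n_gdmr_oocyte=5,
    n_ddmr=8,
    n_coexpr_modules=2,
    module_size=5,
)


@pytest.fixture(scope="session")
def dataset() -> pm.FixtureDataset:
    """Default-scale fixture: ~1.2 Mb, 200 genes, 9 stages x 2 replicates."""
    return pm.simulate_dataset(pm.SimulationConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def small_dataset() -> pm.FixtureDataset:
    return pm.simulate_dataset(pm.SimulationConfig(seed=1, **SMALL_CONFIG))


@pytest.fixture(scope="session")
def tile_methylomes(dataset) -> dict[str, pm.TileMethylome]:
    return {s.sample_id: pm.tile_methylation(s) for s in dataset.samples}


@pytest.fixture(scope="session")
def stage_methylomes(dataset, tile_methylomes) -> dict[str, pm.StageMethylome]:
    out = {}
    for stage in dataset.config.stages:
        reps = [
            tile_methylomes[s]
            for s, st in dataset.truth.sample_to_stage.items()
            if st == stage
        ]
        out[stage] = pm.stage_average(reps, stage)
    return out


@pytest.fixture(scope="session")
def cpg_levels(dataset) -> dict[str, pd.DataFrame]:
    return {s.sample_id: pm.cpg_methylation(s) for s in dataset.samples}


@pytest.fixture(scope="session")
def analysis(dataset, tile_methylomes, stage_methylomes, cpg_levels) -> dict:
    """The full downstream analysis run in memory on the default fixture."""
    truth = dataset.truth
    genes = dataset.annotation.genes
    by_gamete = {
        g: [tile_methylomes[s] for s, st in truth.sample_to_stage.items() if st == g]
        for g in ("sperm", "oocyte")
    }
    cpg_by_gamete = {
        g: [cpg_levels[s] for s, st in truth.sample_to_stage.items() if st == g]
        for g in ("sperm", "oocyte")
    }
    gdmrs = gdmr_mod.call_gdmrs(
        by_gamete["sperm"],
        by_gamete["oocyte"],
        sperm_cpg=cpg_by_gamete["sperm"],
        oocyte_cpg=cpg_by_gamete["oocyte"],
    )
    stage_list = [stage_methylomes[s] for s in dataset.config.stages]
    ddmrs = ddmr_mod.call_ddmrs(stage_list)

    prom_regions = genes[["gene_id", "chrom", "promoter_start", "promoter_end"]].rename(
        columns={"promoter_start": "start", "promoter_end": "end", "gene_id": "region_id"}
    )
    body_regions = ann_mod.gene_body_regions(genes)
    prom_levels = pd.DataFrame(
        {s: ann_mod.region_methylation(stage_methylomes[s], prom_regions)
         for s in dataset.config.stages}
    )
    body_levels = pd.DataFrame(
        {s: ann_mod.region_methylation(stage_methylomes[s], body_regions)
         for s in dataset.config.stages}
    )
    corr_prom = methylation_expression_correlation(prom_levels, dataset.expression)
    corr_body = methylation_expression_correlation(body_levels, dataset.expression)

    filtered = net_mod.filter_genes(dataset.expression)
    pairs = net_mod.pcc_and_fisher(filtered)
    a_prom = gdmr_mod.assign_dmrs_to_genes(ddmrs, genes, region="promoter")
    seed_genes = sorted(set(a_prom["gene_id"]))
    classes = dict(zip(genes.gene_id, genes.gene_class))
    edges, nodes = net_mod.build_network(pairs, seed_genes, gene_classes=classes)
    return {
        "gdmrs": gdmrs,
        "ddmrs": ddmrs,
        "prom_levels": prom_levels,
        "corr_prom": corr_prom,
        "corr_body": corr_body,
        "pairs": pairs,
        "edges": edges,
        "nodes": nodes,
        "seed_genes": seed_genes,
        "n_tested_ddmr": ddmrs.attrs["n_tested"],
    }


def region_overlap_oracle(region, intervals) -> bool:
    """Brute-force >=1 bp half-open overlap check used by several oracles."""
    c, s, e = region
    return any(ic == c and s < ie and e > is_ for ic, is_, ie in intervals)
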