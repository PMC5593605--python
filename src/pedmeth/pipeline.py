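"""End-to-end orchestration: simulate -> quantify -> profile -> DMRs ->
expression coupling -> network -> enrichment, with deterministic seeding,
per-stage outputs, resume bookkeeping, and an auditable run report.

Every tunable threshold the stages use is recorded in the run report; a
rerun with the same config and seed reproduces the deterministic stage
outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann_mod
from . import ddmr as ddmr_mod
from . import evaluate, gdmr, network, quant, simulate
from .errors import ConfigError, DataError
from .expression import load_expression, methylation_expression_correlation

log = logging.getLogger(__name__)

STAGE_ORDER = [
    "simulate",
    "quant",
    "profiles",
    "gdmr",
    "ddmr",
    "correlate",
    "network",
    "enrich",
    "report",
]


@dataclass
class PipelineConfig:
    """Single source of truth for a run: inputs (or a simulation), every
    stage threshold, the output directory and the seed."""

    out_dir: str = "pedmeth_run"
    seed: int = 0
    simulate: simulate.SimulationConfig | None = None
    inputs: dict = field(default_factory=dict)  # paths when not simulating
    min_cov: int = 5
    tile_size: int = 100
    density_window: int = 50
    tss_flank: int = 5000
    tss_window: int = 100
    distal_min_dist: int = 1000
    hi: float = 0.75
    lo: float = 0.25
    fdr: float = 0.05
    kmeans_k: int = 6
    h_threshold: float | None = None
    r_min: float = 0.8
    p_max: float = 0.05
    min_max_expr: float = 5.0
    var_keep_fraction: float = 0.75
    hub_quantile: float = 0.05
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.hi <= self.lo:
            raise ConfigError(f"hi ({self.hi}) must exceed lo ({self.lo})")
        for name, v, lo_v, hi_v in (
            ("fdr", self.fdr, 0.0, 1.0),
            ("p_max", self.p_max, 0.0, 1.0),
            ("var_keep_fraction", self.var_keep_fraction, 0.0, 1.0),
            ("hub_quantile", self.hub_quantile, 0.0, 1.0),
        ):
            if not lo_v < v <= hi_v:
                raise ConfigError(f"{name}={v} outside ({lo_v}, {hi_v}]")
        if self.min_cov < 1 or self.tile_size < 1 or self.kmeans_k < 2:
            raise ConfigError("min_cov/tile_size/kmeans_k out of range")
        if not 0 < self.r_min < 1:
            raise ConfigError("r_min must be in (0, 1)")
        if self.simulate is not None:
            self.simulate.validate()
        elif not self.inputs:
            raise ConfigError("either a simulate block or input paths are required")

    def thresholds(self) -> dict:
        skip = {"out_dir", "simulate", "inputs", "log_level"}
        return {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name not in skip
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg = dataclasses.replace(
                cfg, simulate=simulate.SimulationConfig.from_dict(sim)
            )
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_dict()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


# ---------------------------------------------------------------------------


class PipelineRun:
    """Executes stages in dependency order over a run directory."""

    def __init__(self, config: PipelineConfig):
        config.validate()
        self.cfg = config
        self.out = Path(config.out_dir)
        self.timings: dict[str, float] = {}
        self.notes: dict[str, dict] = {}

    # -- helpers -----------------------------------------------------------

    def _paths(self) -> dict:
        cfg = self.cfg
        if cfg.simulate is not None:
            fx = self.out / "fixture"
            return {
                "coverage_dir": fx / "coverage",
                "sample_stages": fx / "truth" / "sample_stages.tsv",
                "genes_gtf": fx / "annotation" / "genes.gtf",
                "features": {
                    n: fx / "annotation" / f"{n}.bed" for n in ("cgi", "exon", "intron")
                },
                "expression": fx / "expression" / "expression.tsv",
                "expression_samples": fx / "expression" / "samples.tsv",
                "term_table": None,
            }
        inp = cfg.inputs
        return {
            "coverage_dir": Path(inp["coverage_dir"]),
            "sample_stages": Path(inp["sample_stages"]),
            "genes_gtf": Path(inp["genes_gtf"]),
            "features": {n: Path(p) for n, p in inp.get("features", {}).items()},
            "expression": Path(inp["expression"]),
            "expression_samples": Path(inp["expression_samples"]),
            "term_table": Path(inp["term_table"]) if inp.get("term_table") else None,
        }

    def _sample_stages(self) -> dict[str, str]:
        df = pd.read_csv(self._paths()["sample_stages"], sep="\t")
        return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))

    def _stage_labels(self) -> list[str]:
        if self.cfg.simulate is not None:
            return list(self.cfg.simulate.stages)
        seen: list[str] = []
        for s in self._sample_stages().values():
            if s not in seen:
                seen.append(s)
        return seen

    def _load_tiles(self, sample: str) -> quant.TileMethylome:
        df = pd.read_csv(self.out / "quant" / f"tiles_{sample}.tsv", sep="\t")
        return quant.TileMethylome(sample_id=sample, df=df)

    def _load_stage(self, stage: str) -> quant.StageMethylome:
        df = pd.read_csv(self.out / "quant" / f"stage_{stage}.tsv", sep="\t")
        return quant.StageMethylome(stage=stage, df=df, n_replicates=0)

    def _load_genes(self) -> pd.DataFrame:
        return ann_mod.load_genes(self._paths()["genes_gtf"])

    def _load_features(self, genes: pd.DataFrame) -> dict[str, pd.DataFrame]:
        feats = {}
        for name, path in self._paths()["features"].items():
            feats[name] = pd.read_csv(
                path, sep="\t", header=None, names=["chrom", "start", "end"]
            )
        feats["promoter"] = genes[["chrom", "promoter_start", "promoter_end"]].rename(
            columns={"promoter_start": "start", "promoter_end": "end"}
        )
        return feats

    # -- stages ------------------------------------------------------------

    def stage_simulate(self) -> None:
        if self.cfg.simulate is None:
            return
        sim_cfg = dataclasses.replace(self.cfg.simulate, seed=self.cfg.seed)
        dataset = simulate.simulate_dataset(sim_cfg)
        simulate.write_fixture(dataset, self.out / "fixture")
        self.notes["simulate"] = {
            "n_genes": len(dataset.annotation.genes),
            "n_samples": len(dataset.samples),
        }

    def stage_quant(self) -> None:
        cfg = self.cfg
        paths = self._paths()
        qdir = self.out / "quant"
        qdir.mkdir(parents=True, exist_ok=True)
        sample_stage = self._sample_stages()
        by_stage: dict[str, list[quant.TileMethylome]] = {}
        summary = []
        for sample, stage in sample_stage.items():
            counts = quant.load_coverage(paths["coverage_dir"] / f"{sample}.cov", sample)
            tm = quant.tile_methylation(
                counts,
                tile_size=cfg.tile_size,
                min_cov=cfg.min_cov,
                density_window=cfg.density_window,
            )
            tm.df.to_csv(qdir / f"tiles_{sample}.tsv", sep="\t", index=False)
            by_stage.setdefault(stage, []).append(tm)
            fl, fi, fh = quant.status_fractions(tm.df["level"])
            summary.append(
                {
                    "sample": sample,
                    "stage": stage,
                    "mean_level": quant.sample_mean_level(tm),
                    "n_tiles": len(tm.df),
                    "frac_low": fl,
                    "frac_intermediate": fi,
                    "frac_high": fh,
                }
            )
        for stage, reps in by_stage.items():
            sm = quant.stage_average(reps, stage)
            sm.df.to_csv(qdir / f"stage_{stage}.tsv", sep="\t", index=False)
        pd.DataFrame(summary).to_csv(qdir / "sample_summary.tsv", sep="\t", index=False)

    def stage_profiles(self) -> None:
        cfg = self.cfg
        pdir = self.out / "profiles"
        pdir.mkdir(parents=True, exist_ok=True)
        genes = self._load_genes()
        lnc = genes[genes.gene_class == "lncRNA"].reset_index(drop=True)
        cod = genes[genes.gene_class == "coding"].reset_index(drop=True)
        lnc_distal = ann_mod.filter_distal_lncrna(lnc, cod, cfg.distal_min_dist)
        stages = self._stage_labels()
        ref_stage = "sperm" if "sperm" in stages else stages[0]
        sm = self._load_stage(ref_stage)
        ks = {}
        for label, sub in (("lncRNA", lnc_distal), ("coding", cod)):
            for value_col, tag in (("level", "methylation"), ("cpg_density", "cpg_density")):
                source = sm.df if value_col == "level" else self._tile_density_frame()
                prof = ann_mod.tss_profile(
                    source,
                    sub,
                    flank=cfg.tss_flank,
                    window=cfg.tss_window,
                    value_col=value_col,
                )
                prof.to_csv(pdir / f"tss_{tag}_{label}.tsv", sep="\t", index=False)
        prom = genes[["gene_id", "gene_class", "chrom", "promoter_start", "promoter_end"]]
        prom = prom.rename(
            columns={"promoter_start": "start", "promoter_end": "end", "gene_id": "region_id"}
        )
        prom_levels = {}
        for stage in stages:
            prom_levels[stage] = ann_mod.region_methylation(
                self._load_stage(stage), prom, tile_size=cfg.tile_size
            )
        prom_df = pd.DataFrame(prom_levels)
        prom_df.insert(0, "gene_class", prom.set_index("region_id")["gene_class"])
        prom_df.rename_axis("gene_id").to_csv(pdir / "promoter_methylation.tsv", sep="\t")
        for value_name, (a, b) in {
            "tss_methylation": (
                self._tss_values(sm.df, lnc_distal, "level"),
                self._tss_values(sm.df, cod, "level"),
            ),
            "promoter_level": (
                prom_df.loc[prom_df.gene_class == "lncRNA", ref_stage].dropna(),
                prom_df.loc[prom_df.gene_class == "coding", ref_stage].dropna(),
            ),
        }.items():
            if len(a) >= 2 and len(b) >= 2:
                d, p = ann_mod.ks_compare(a, b)
                ks[value_name] = {"D": d, "p": p}
        with open(pdir / "ks_tests.json", "w") as fh:
            json.dump(ks, fh, indent=2)
        self.notes["profiles"] = {
            "n_lncrna_distal": len(lnc_distal),
            "ref_stage": ref_stage,
        }

    def _tile_density_frame(self) -> pd.DataFrame:
        # density is sample-invariant here; take the first sample's tiles
        sample = next(iter(self._sample_stages()))
        return self._load_tiles(sample).df

    @staticmethod
    def _tss_values(tiles: pd.DataFrame, genes: pd.DataFrame, col: str) -> np.ndarray:
        vals = []
        for r in genes.itertuples():
            sub = tiles[
                (tiles.chrom == r.chrom)
                & (tiles.start < r.promoter_end)
                & (tiles.end > r.promoter_start)
            ]
            vals.extend(sub[col].tolist())
        return np.asarray(vals)

    def stage_gdmr(self) -> None:
        cfg = self.cfg
        gdir = self.out / "gdmr"
        gdir.mkdir(parents=True, exist_ok=True)
        sample_stage = self._sample_stages()
        paths = self._paths()
        sperm = [self._load_tiles(s) for s, st in sample_stage.items() if st == "sperm"]
        oocyte = [self._load_tiles(s) for s, st in sample_stage.items() if st == "oocyte"]

        def _cpg_levels(gamete: str) -> list[pd.DataFrame]:
            out = []
            for s, st in sample_stage.items():
                if st == gamete:
                    counts = quant.load_coverage(paths["coverage_dir"] / f"{s}.cov", s)
                    out.append(quant.cpg_methylation(counts, min_cov=cfg.min_cov))
            return out

        dmrs = gdmr.call_gdmrs(
            sperm,
            oocyte,
            hi=cfg.hi,
            lo=cfg.lo,
            fdr=cfg.fdr,
            method="cpg",
            sperm_cpg=_cpg_levels("sperm"),
            oocyte_cpg=_cpg_levels("oocyte"),
            tile_size=cfg.tile_size,
        )
        stage_ms = [self._load_stage(s) for s in self._stage_labels()]
        if len(dmrs) >= cfg.kmeans_k:
            mat = gdmr.dmr_stage_matrix(dmrs, stage_ms)
            labels, centroids = gdmr.cluster_dynamics(mat, k=cfg.kmeans_k, seed=cfg.seed)
            dmrs["cluster_id"] = labels
            centroids.to_csv(gdir / "cluster_centroids.tsv", sep="\t")
        else:
            log.warning("only %d G-DMRs: skipping k-means clustering", len(dmrs))
            dmrs["cluster_id"] = 0
        dmrs.to_csv(gdir / "gdmrs.tsv", sep="\t", index=False)
        with open(gdir / "gdmrs.bed", "w") as fh:
            for r in dmrs.itertuples():
                score = int(1000 * abs(r.mean_sperm - r.mean_oocyte))
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.gamete}\t{score}\t+\n"
                )
        genes = self._load_genes()
        features = self._load_features(genes)
        universe = gdmr._level_matrix(sperm).index.intersection(
            gdmr._level_matrix(oocyte).index
        )
        uni_df = pd.DataFrame(list(universe), columns=["chrom", "start", "end"])
        labeled = ann_mod.assign_tiles(uni_df, features, tile_size=cfg.tile_size)
        called_keys = set(zip(dmrs.chrom, dmrs.start))
        enrich_frames = []
        for gamete in ("sperm", "oocyte"):
            keys = set(
                zip(dmrs[dmrs.gamete == gamete].chrom, dmrs[dmrs.gamete == gamete].start)
            )
            mask = np.array(
                [(c, s) in keys for c, s in zip(uni_df.chrom, uni_df.start)]
            )
            if mask.sum() == 0:
                continue
            e = gdmr.annotation_enrichment(
                labeled, mask, ["promoter", "exon", "intron", "cgi"]
            )
            e.insert(0, "gamete", gamete)
            enrich_frames.append(e)
        if enrich_frames:
            pd.concat(enrich_frames, ignore_index=True).to_csv(
                gdir / "enrichment.tsv", sep="\t", index=False
            )
        bias = {}
        for region in ("body", "promoter"):
            assigned = gdmr.assign_dmrs_to_genes(dmrs, genes, region=region)
            assigned.to_csv(gdir / f"assigned_{region}.tsv", sep="\t", index=False)
            try:
                b = gdmr.parental_bias(assigned)
                bias[region] = {
                    "sperm_fraction": b["sperm_fraction"],
                    "chi2": b["chi2"],
                    "p": b["p"],
                }
            except DataError as exc:
                bias[region] = {"error": str(exc)}
        with open(gdir / "parental_bias.json", "w") as fh:
            json.dump(bias, fh, indent=2)
        self.notes["gdmr"] = {"n_called": len(dmrs), "n_universe": len(universe)}

    def stage_ddmr(self) -> None:
        cfg = self.cfg
        ddir = self.out / "ddmr"
        ddir.mkdir(parents=True, exist_ok=True)
        stage_ms = [self._load_stage(s) for s in self._stage_labels()]
        called = ddmr_mod.call_ddmrs(stage_ms, threshold=cfg.h_threshold)
        called.to_csv(ddir / "ddmrs.tsv", sep="\t", index=False)
        with open(ddir / "ddmrs.bed", "w") as fh:
            for r in called.itertuples():
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.direction}\t"
                    f"{int(100 * r.H)}\t+\n"
                )
        genes = self._load_genes()
        a_body = gdmr.assign_dmrs_to_genes(called, genes, region="body")
        a_prom = gdmr.assign_dmrs_to_genes(called, genes, region="promoter")
        a_body.to_csv(ddir / "assigned_body.tsv", sep="\t", index=False)
        a_prom.to_csv(ddir / "assigned_promoter.tsv", sep="\t", index=False)
        summary = ddmr_mod.ddmr_class_summary(a_body, a_prom)
        summary["threshold"] = called.attrs.get("threshold")
        summary["n_tested"] = called.attrs.get("n_tested")
        with open(ddir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
        self.notes["ddmr"] = {
            "n_called": len(called),
            "threshold": called.attrs.get("threshold"),
            "n_tested": called.attrs.get("n_tested"),
        }

    def stage_correlate(self) -> None:
        cfg = self.cfg
        cdir = self.out / "correlate"
        cdir.mkdir(parents=True, exist_ok=True)
        paths = self._paths()
        smap_df = pd.read_csv(paths["expression_samples"], sep="\t")
        smap = dict(zip(smap_df.iloc[:, 0], smap_df.iloc[:, 1]))
        expr = load_expression(paths["expression"], smap)
        genes = self._load_genes()
        stages = self._stage_labels()
        region_tables = {
            "promoter": genes[
                ["gene_id", "chrom", "promoter_start", "promoter_end"]
            ].rename(
                columns={
                    "promoter_start": "start",
                    "promoter_end": "end",
                    "gene_id": "region_id",
                }
            ),
            "genebody": ann_mod.gene_body_regions(genes, exclude_promoter=True),
        }
        for region, regions in region_tables.items():
            levels = pd.DataFrame(
                {
                    st: ann_mod.region_methylation(
                        self._load_stage(st), regions, tile_size=cfg.tile_size
                    )
                    for st in stages
                }
            )
            levels.rename_axis("gene_id").to_csv(
                cdir / f"{region}_methylation.tsv", sep="\t"
            )
            corr = methylation_expression_correlation(levels, expr)
            corr.to_csv(cdir / f"correlation_{region}.tsv", sep="\t", index=False)

    def stage_network(self) -> None:
        cfg = self.cfg
        ndir = self.out / "network"
        ndir.mkdir(parents=True, exist_ok=True)
        paths = self._paths()
        smap_df = pd.read_csv(paths["expression_samples"], sep="\t")
        smap = dict(zip(smap_df.iloc[:, 0], smap_df.iloc[:, 1]))
        expr = load_expression(paths["expression"], smap)
        filtered = network.filter_genes(
            expr, min_max_expr=cfg.min_max_expr, var_keep_fraction=cfg.var_keep_fraction
        )
        pairs = network.pcc_and_fisher(filtered)
        a_prom = pd.read_csv(self.out / "ddmr" / "assigned_promoter.tsv", sep="\t")
        seed_genes = sorted(set(a_prom["gene_id"])) if not a_prom.empty else []
        genes = self._load_genes()
        classes = dict(zip(genes.gene_id, genes.gene_class))
        if not seed_genes:
            log.warning("no promoter D-DMR genes: network will be empty")
            edges = pairs.iloc[0:0].copy()
            edges["seed_flag"] = []
            nodes = pd.DataFrame(columns=["gene_id", "gene_class", "is_seed"])
        else:
            edges, nodes = network.build_network(
                pairs, seed_genes, r_min=cfg.r_min, p_max=cfg.p_max, gene_classes=classes
            )
        edges.to_csv(ndir / "edges.tsv", sep="\t", index=False)
        nodes.to_csv(ndir / "nodes.tsv", sep="\t", index=False)
        g = network.to_graph(edges, nodes)
        import networkx as nx

        nx.write_graphml(g, ndir / "network.graphml")
        topo = network.topology(g, hub_quantile=cfg.hub_quantile)
        with open(ndir / "topology.json", "w") as fh:
            json.dump(
                {
                    "n_nodes": topo["n_nodes"],
                    "n_edges": topo["n_edges"],
                    "hubs": list(map(str, topo["hubs"])),
                    "component_sizes": topo["component_sizes"],
                    "n_lncrna": int((nodes.gene_class == "lncRNA").sum()),
                    "n_coding": int((nodes.gene_class == "coding").sum()),
                },
                fh,
                indent=2,
            )
        self.notes["network"] = {
            "n_nodes": topo["n_nodes"],
            "n_edges": topo["n_edges"],
            "n_filtered_genes": len(filtered),
        }

    def stage_enrich(self) -> None:
        edir = self.out / "enrich"
        edir.mkdir(parents=True, exist_ok=True)
        paths = self._paths()
        term_path = paths["term_table"]
        if term_path is None and self.cfg.simulate is not None:
            term_path = self.out / "fixture" / "truth" / "modules.tsv"
        if term_path is None or not Path(term_path).exists():
            log.info("no term table: enrichment stage writes an empty table")
            pd.DataFrame(
                columns=["term", "overlap", "set_size", "query_size", "universe",
                         "fold_enrichment", "p", "q"]
            ).to_csv(edir / "enrichment.tsv", sep="\t", index=False)
            return
        terms = pd.read_csv(term_path, sep="\t")[["module_id", "gene_id"]] \
            if "module_id" in pd.read_csv(term_path, sep="\t", nrows=0).columns \
            else pd.read_csv(term_path, sep="\t", header=None)
        nodes = pd.read_csv(self.out / "network" / "nodes.tsv", sep="\t")
        smap_df = pd.read_csv(paths["expression_samples"], sep="\t")
        smap = dict(zip(smap_df.iloc[:, 0], smap_df.iloc[:, 1]))
        expr = load_expression(paths["expression"], smap)
        universe = list(expr.df.index)
        query = [g for g in nodes.get("gene_id", []) if g in set(universe)]
        if not query:
            log.info("empty network: enrichment skipped")
            pd.DataFrame().to_csv(edir / "enrichment.tsv", sep="\t", index=False)
            return
        res = network.geneset_enrichment(query, terms, universe)
        res.to_csv(edir / "enrichment.tsv", sep="\t", index=False)

    def stage_report(self) -> None:
        report = {
            "thresholds": self.cfg.thresholds(),
            "seed": self.cfg.seed,
            "stage_timings_s": self.timings,
            "stage_notes": self.notes,
        }
        if self.cfg.simulate is not None:
            report["recovery"] = self._recovery_report()
        with open(self.out / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)

    def _recovery_report(self) -> dict:
        fx = self.out / "fixture" / "truth"
        truth_g = pd.read_csv(fx / "gdmrs.tsv", sep="\t")
        truth_d = pd.read_csv(fx / "ddmrs.tsv", sep="\t")
        modules = pd.read_csv(fx / "modules.tsv", sep="\t")
        called_g = pd.read_csv(self.out / "gdmr" / "gdmrs.tsv", sep="\t")
        called_d = pd.read_csv(self.out / "ddmr" / "ddmrs.tsv", sep="\t")
        edges = pd.read_csv(self.out / "network" / "edges.tsv", sep="\t")
        corr = pd.read_csv(
            self.out / "correlate" / "correlation_promoter.tsv", sep="\t"
        )
        n_tested = self.notes.get("ddmr", {}).get("n_tested")
        if n_tested is None:
            with open(self.out / "ddmr" / "summary.json") as fh:
                n_tested = int(json.load(fh)["n_tested"])
        rec = {
            "gdmr": evaluate.gdmr_recovery(called_g, truth_g, self.cfg.tile_size),
            "ddmr": evaluate.ddmr_recovery(
                called_d, truth_d, int(n_tested), self.cfg.tile_size, exclude=truth_g
            ),
            "network": evaluate.module_edge_precision(edges, modules),
            "promoter_corr_negative_fraction": float(
                (corr["r"].dropna() < 0).mean()
            ),
        }
        return rec

    # -- driver ------------------------------------------------------------

    STAGE_OUTPUTS = {
        "simulate": ["fixture/manifest.json"],
        "quant": ["quant/sample_summary.tsv"],
        "profiles": ["profiles/ks_tests.json"],
        "gdmr": ["gdmr/gdmrs.tsv"],
        "ddmr": ["ddmr/ddmrs.tsv", "ddmr/assigned_promoter.tsv"],
        "correlate": ["correlate/correlation_promoter.tsv"],
        "network": ["network/edges.tsv", "network/topology.json"],
        "enrich": ["enrich/enrichment.tsv"],
        "report": ["run_report.json"],
    }

    def run(self, resume: bool = False, until: str | None = None) -> Path:
        self.out.mkdir(parents=True, exist_ok=True)
        upstream_ran = False
        for stage in STAGE_ORDER:
            if stage == "simulate" and self.cfg.simulate is None:
                continue
            outputs = [self.out / p for p in self.STAGE_OUTPUTS[stage]]
            if resume and not upstream_ran and all(p.exists() for p in outputs):
                log.info("stage %s: outputs present, skipped (resume)", stage)
                if until is not None and stage == until:
                    break
                continue
            t0 = time.perf_counter()
            log.info("stage %s: running", stage)
            try:
                getattr(self, f"stage_{stage}")()
            except (ConfigError, DataError):
                raise
            except Exception as exc:  # annotate which stage failed
                raise DataError(f"stage {stage} failed: {exc}") from exc
            self.timings[stage] = round(time.perf_counter() - t0, 3)
            upstream_ran = True
            if until is not None and stage == until:
                break
        return self.out


def run_pipeline(
    config: PipelineConfig, resume: bool = False, until: str | None = None
) -> Path:
    """Run all stages (or up to `until`) and return the run directory."""
    return PipelineRun(config).run(resume=resume, until=until)


def run_demo(out_dir: str | Path, seed: int = 0, **sim_overrides) -> Path:
    """Simulate a full fixture and run the entire pipeline against it,
    finishing with a recovery report scored against the ground truth."""
    sim = simulate.SimulationConfig(seed=seed, **sim_overrides)
    cfg = PipelineConfig(out_dir=str(out_dir), seed=seed, simulate=sim)
    return run_pipeline(cfg)
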