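"""Synthetic RRBS + single-cell expression fixtures with planted structure.

The generator emulates the statistical shape of a pre-implantation
developmental series: a genome-wide demethylation wave that bottoms out at
the 2-cell stage and recovers after implantation, gamete-specific DMRs
(hypermethylated in one gamete, hypomethylated in the other), developmental-
specific DMRs methylated in essentially one stage, CpG-poor lncRNA promoters
that run hotter than protein-coding promoters, a negative promoter-
methylation -> expression coupling, and planted co-expression modules.
Every planted feature is emitted in a GroundTruth table so that downstream
callers can be scored for recovery.

Coordinates are 0-based half-open internally; file writers emit each
format's native dialect (Bismark coverage is 1-based inclusive).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .expression import ExpressionMatrix
from .quant import CpGCounts

log = logging.getLogger(__name__)

DEFAULT_STAGES = (
    "sperm",
    "oocyte",
    "zygote",
    "2cell",
    "4cell",
    "8cell",
    "morula",
    "blastocyst",
    "postimplantation",
)

#: Background tile-methylation trajectory of the demethylation wave:
#: high in sperm, intermediate in oocyte, minimum at the 2-cell stage,
#: re-methylated after implantation.
STAGE_BASELINE = {
    "sperm": 0.80,
    "oocyte": 0.55,
    "zygote": 0.45,
    "2cell": 0.25,
    "4cell": 0.30,
    "8cell": 0.35,
    "morula": 0.42,
    "blastocyst": 0.48,
    "postimplantation": 0.75,
}

GAMETES = ("sperm", "oocyte")

#: Fraction of a promoter's per-gene methylation propensity that persists
#: through the demethylation wave (promoters, unlike bulk genome, retain a
#: residual methylation floor at the cleavage-stage nadir).
PROMOTER_FLOOR = 0.35


def _default_chrom_sizes() -> dict[str, int]:
    return {"chr1": 600_000, "chr2": 600_000}


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of one synthetic dataset.

    Methylation noise is beta-binomial: the per-CpG success probability is
    drawn from Beta(m*kappa, (1-m)*kappa) around the regional stage mean m,
    with kappa = 1 / beta_dispersion; coverage is Poisson(coverage_mean)
    truncated at zero.
    """

    stages: tuple[str, ...] = DEFAULT_STAGES
    replicates_per_stage: int = 2
    n_coding: int = 120
    n_lncrna: int = 80
    chrom_sizes: dict[str, int] = field(default_factory=_default_chrom_sizes)
    coverage_mean: float = 30.0
    beta_dispersion: float = 0.01
    n_gdmr_sperm: int = 20
    n_gdmr_oocyte: int = 20
    n_ddmr: int = 30
    coupling_slope: float = -2.0
    gene_body_slope: float = 1.5
    n_coexpr_modules: int = 3
    module_size: int = 8
    module_strength: float = 2.0
    expr_noise_sd: float = 0.5
    cells_per_stage: int = 8
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not self.stages:
            raise ConfigError("stages must be a nonempty list")
        for g in GAMETES:
            if g not in self.stages:
                raise ConfigError(f"stages must contain gamete label {g!r}")
        if not self.chrom_sizes:
            raise ConfigError("chrom_sizes must be nonempty")
        for name in (
            "n_coding",
            "n_lncrna",
            "n_gdmr_sperm",
            "n_gdmr_oocyte",
            "n_ddmr",
            "n_coexpr_modules",
            "cells_per_stage",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_coding + self.n_lncrna == 0:
            raise ConfigError("need at least one gene")
        if self.coverage_mean <= 0:
            raise ConfigError("coverage_mean must be > 0")
        if self.beta_dispersion <= 0:
            raise ConfigError("beta_dispersion must be > 0")
        if self.n_coexpr_modules > 0 and self.module_size < 3:
            raise ConfigError("module_size must be >= 3 when modules are planted")
        if self.n_coexpr_modules > 0 and self.n_ddmr < 2 * self.n_coexpr_modules:
            raise ConfigError(
                "n_ddmr must be >= 2 * n_coexpr_modules so every module can be "
                "seeded by promoter D-DMR genes"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)


@dataclass
class GenomeAnnotation:
    """Gene models plus CpG positions and feature interval sets."""

    genes: pd.DataFrame  # gene_id, gene_class, chrom, strand, start, end, tss,
    #                      promoter_start, promoter_end, exon_starts, exon_ends
    cpg_positions: dict[str, np.ndarray]
    features: dict[str, pd.DataFrame]  # name -> (chrom, start, end)
    chrom_sizes: dict[str, int]


@dataclass
class GroundTruth:
    """Everything that was planted, for recovery scoring downstream."""

    gdmrs: pd.DataFrame  # chrom, start, end, gamete, host_gene, host_class, location
    ddmrs: pd.DataFrame  # chrom, start, end, stage, direction, host_gene,
    #                      host_class, location, module_id
    modules: pd.DataFrame  # module_id, gene_id, is_seed
    coupling: pd.DataFrame  # gene_id, promoter_slope, body_slope
    promoter_meth: pd.DataFrame  # genes x stages true regional means
    body_meth: pd.DataFrame
    sample_to_stage: dict[str, str]


@dataclass
class FixtureDataset:
    config: SimulationConfig
    annotation: GenomeAnnotation
    samples: list[CpGCounts]
    truth: GroundTruth
    expression: ExpressionMatrix


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_MIN_SLOT = 6000  # bp per gene: body <=3000 plus promoter flank and spacing


def generate_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """Place non-overlapping gene models and CpG sites on each chromosome.

    lncRNA promoters receive a lower CpG-placement rate than protein-coding
    promoters; a fraction of promoters carry a CpG island with a high rate.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])

    n_genes = config.n_coding + config.n_lncrna
    chroms = list(config.chrom_sizes)
    total = sum(config.chrom_sizes.values())
    # largest-remainder apportionment of genes to chromosomes
    quota = {c: config.chrom_sizes[c] * n_genes / total for c in chroms}
    counts = {c: int(np.floor(quota[c])) for c in chroms}
    rem = n_genes - sum(counts.values())
    for c in sorted(chroms, key=lambda c: quota[c] - counts[c], reverse=True)[:rem]:
        counts[c] += 1

    classes = np.array(
        ["coding"] * config.n_coding + ["lncRNA"] * config.n_lncrna, dtype=object
    )
    classes = rng.permutation(classes)

    rows = []
    gi = 0
    n_pc = n_lnc = 0
    for chrom in chroms:
        nc = counts[chrom]
        if nc == 0:
            continue
        slot = config.chrom_sizes[chrom] // nc
        if slot < _MIN_SLOT:
            raise ConfigError(
                f"chromosome {chrom} too short: {config.chrom_sizes[chrom]} bp "
                f"for {nc} genes (need >= {_MIN_SLOT} bp per gene)"
            )
        for i in range(nc):
            slot_start = i * slot
            avail = slot - 2400  # 1200-bp margins protect promoters and spacing
            body_len = int(rng.integers(1500, min(3000, avail - 1) + 1))
            start = slot_start + 1200 + int(rng.integers(0, avail - body_len + 1))
            end = start + body_len
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end
            n_ex = int(rng.integers(2, 5))
            nseg = 2 * n_ex - 1
            w = rng.dirichlet(np.ones(nseg))
            seg = 60 + np.floor(w * (body_len - 60 * nseg)).astype(int)
            seg[-1] += body_len - seg.sum()
            bounds = start + np.concatenate([[0], np.cumsum(seg)])
            exon_starts = bounds[0:nseg:2]
            exon_ends = bounds[1 : nseg + 1 : 2]
            cls = classes[gi]
            if cls == "coding":
                n_pc += 1
                gene_id = f"PC{n_pc:04d}"
            else:
                n_lnc += 1
                gene_id = f"LNC{n_lnc:04d}"
            rows.append(
                {
                    "gene_id": gene_id,
                    "gene_class": cls,
                    "chrom": chrom,
                    "strand": strand,
                    "start": start,
                    "end": end,
                    "tss": tss,
                    "promoter_start": tss - 1000,
                    "promoter_end": tss + 1000,
                    "exon_starts": ",".join(map(str, exon_starts)),
                    "exon_ends": ",".join(map(str, exon_ends)),
                }
            )
            gi += 1
    genes = pd.DataFrame(rows)

    # CpG placement: piecewise-constant Bernoulli rate per bp
    cgi_rows = []
    cpg_positions: dict[str, np.ndarray] = {}
    for chrom, length in config.chrom_sizes.items():
        rate = np.full(length, 0.005)
        sub = genes[genes.chrom == chrom]
        for r in sub.itertuples():
            rate[r.start : r.end] = 0.010
        for r in sub.itertuples():
            if r.gene_class == "coding":
                prom_rate = rng.uniform(0.030, 0.050)
            else:
                prom_rate = rng.uniform(0.010, 0.022)
            a, b = max(0, r.promoter_start), min(length, r.promoter_end)
            rate[a:b] = prom_rate
        for r in sub.itertuples():
            p_cgi = 0.6 if r.gene_class == "coding" else 0.2
            if rng.random() < p_cgi:
                a, b = max(0, r.tss - 400), min(length, r.tss + 400)
                rate[a:b] = 0.08
                cgi_rows.append({"chrom": chrom, "start": a, "end": b})
        cpg_positions[chrom] = np.flatnonzero(rng.random(length) < rate)

    exon_rows, intron_rows = [], []
    for r in genes.itertuples():
        es = [int(x) for x in r.exon_starts.split(",")]
        ee = [int(x) for x in r.exon_ends.split(",")]
        for a, b in zip(es, ee):
            exon_rows.append({"chrom": r.chrom, "start": a, "end": b})
        for a, b in zip(ee[:-1], es[1:]):
            intron_rows.append({"chrom": r.chrom, "start": a, "end": b})

    features = {
        "cgi": pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"]),
        "exon": pd.DataFrame(exon_rows, columns=["chrom", "start", "end"]),
        "intron": pd.DataFrame(intron_rows, columns=["chrom", "start", "end"]),
        "promoter": genes[["chrom", "promoter_start", "promoter_end"]].rename(
            columns={"promoter_start": "start", "promoter_end": "end"}
        ),
    }
    return GenomeAnnotation(
        genes=genes,
        cpg_positions=cpg_positions,
        features=features,
        chrom_sizes=dict(config.chrom_sizes),
    )


# ---------------------------------------------------------------------------
# methylomes
# ---------------------------------------------------------------------------


def _stage_baseline(stages: tuple[str, ...]) -> np.ndarray:
    return np.array([STAGE_BASELINE.get(s, 0.5) for s in stages])


def _gdmr_trajectory(stages: tuple[str, ...], gamete: str) -> np.ndarray:
    """Planted gamete-specific DMR: hot in its gamete, cold in the other.

    Sperm-specific regions lose methylation rapidly after fertilization and
    re-methylate post-implantation; oocyte-specific regions persist at
    imprint-like intermediate levels through cleavage.
    """
    out = []
    for s in stages:
        if s == gamete:
            out.append(0.95)
        elif s in GAMETES:
            out.append(0.03)
        elif s == "postimplantation":
            out.append(0.70 if gamete == "sperm" else 0.80)
        elif gamete == "oocyte":
            out.append(0.50)
        elif s == "zygote":
            out.append(0.55)
        else:
            out.append(0.07)
    return np.array(out)


def _ddmr_trajectory(
    stages: tuple[str, ...], target_stage: str, direction: str
) -> np.ndarray:
    hi, lo = (0.90, 0.05) if direction == "hyper" else (0.05, 0.90)
    return np.array([hi if s == target_stage else lo for s in stages])


class _RegionPlanner:
    """Pick disjoint, CpG-bearing, tile-aligned regions inside host genes."""

    def __init__(self, annotation: GenomeAnnotation, rng, tile_size=100, n_tiles=3):
        self.ann = annotation
        self.rng = rng
        self.tile_size = tile_size
        self.width = tile_size * n_tiles
        self.used: set[tuple[str, int]] = set()

    def place(self, gene_row, where: str) -> tuple[str, int, int] | None:
        ts = self.tile_size
        if where == "promoter":
            iv = (gene_row.promoter_start, gene_row.promoter_end)
        else:
            iv = (gene_row.start, gene_row.end)
        chrom = gene_row.chrom
        pos = self.ann.cpg_positions[chrom]
        first = -(-max(iv[0], 0) // ts)  # first tile fully inside
        last = (iv[1] - self.width) // ts
        cands = []
        for k in range(first, last + 1):
            s, e = k * ts, k * ts + self.width
            tiles = {(chrom, t) for t in range(k, k + self.width // ts)}
            if tiles & self.used:
                continue
            n_cpg = np.searchsorted(pos, e) - np.searchsorted(pos, s)
            if n_cpg >= 1:
                cands.append((n_cpg, k, tiles))
        if not cands:
            return None
        good = [c for c in cands if c[0] >= 3] or cands
        n_cpg, k, tiles = good[int(self.rng.integers(len(good)))]
        self.used |= tiles
        return chrom, k * ts, k * ts + self.width


def simulate_methylomes(
    annotation: GenomeAnnotation, config: SimulationConfig
) -> tuple[list[CpGCounts], GroundTruth]:
    """Draw per-sample CpG counts around planted regional stage means.

    Returns one CpGCounts per (stage, replicate) sample plus the GroundTruth
    describing every planted G-DMR, D-DMR, co-expression module, and the
    true per-gene regional methylation used later by the expression model.
    """
    config.validate()
    if config.replicates_per_stage < 2:
        raise ConfigError(
            "replicates_per_stage must be >= 2: the gamete DMR t-test "
            "requires biological replicates"
        )
    rng = np.random.default_rng([config.seed, 2])
    genes = annotation.genes
    stages = config.stages
    S = len(stages)
    base = _stage_baseline(stages)

    # per-gene methylation propensities; lncRNA promoters run hotter
    is_lnc = (genes.gene_class == "lncRNA").to_numpy()
    prom_mult = np.where(
        is_lnc, rng.uniform(0.25, 0.90, len(genes)), rng.uniform(0.05, 0.60, len(genes))
    )
    body_mult = rng.uniform(0.40, 1.00, len(genes))

    # ---- plan planted regions -------------------------------------------
    planner = _RegionPlanner(annotation, rng)
    pools = {
        "lncRNA": list(rng.permutation(np.flatnonzero(is_lnc))),
        "coding": list(rng.permutation(np.flatnonzero(~is_lnc))),
    }

    def take_host(cls: str) -> int:
        if not pools[cls]:
            cls = "lncRNA" if cls == "coding" else "coding"
        if not pools[cls]:
            raise ConfigError("not enough genes to host all planted regions")
        return int(pools[cls].pop())

    embryo_stages = [s for s in stages if s not in GAMETES] or list(stages)

    gdmr_rows = []
    for gamete, n_dmr, lnc_frac in (
        ("sperm", config.n_gdmr_sperm, 0.67),
        ("oocyte", config.n_gdmr_oocyte, 0.49),
    ):
        n_lnc = int(round(lnc_frac * n_dmr))
        for j in range(n_dmr):
            cls = "lncRNA" if j < n_lnc else "coding"
            where = "promoter" if j % 3 == 0 else "body"
            for _ in range(10):
                g = take_host(cls)
                placed = planner.place(genes.iloc[g], where)
                if placed:
                    break
            else:
                raise ConfigError(f"could not place planted {gamete} G-DMR {j}")
            chrom, s0, e0 = placed
            gdmr_rows.append(
                {
                    "chrom": chrom,
                    "start": s0,
                    "end": e0,
                    "gamete": gamete,
                    "host_gene": genes.iloc[g].gene_id,
                    "host_class": cls,
                    "location": where,
                }
            )

    # modules first so their seed genes get promoter D-DMRs
    module_rows, ddmr_rows = [], []
    n_seeds = 2
    for mid in range(config.n_coexpr_modules):
        members = [take_host("lncRNA") for _ in range(n_seeds)]
        for j in range(config.module_size - n_seeds):
            members.append(take_host("lncRNA" if j % 2 else "coding"))
        for rank, g in enumerate(members):
            module_rows.append(
                {
                    "module_id": f"M{mid + 1}",
                    "gene_id": genes.iloc[g].gene_id,
                    "is_seed": rank < n_seeds,
                }
            )
        for rank in range(n_seeds):
            g = members[rank]
            placed = planner.place(genes.iloc[g], "promoter")
            if placed is None:
                raise ConfigError("could not place module-seed promoter D-DMR")
            chrom, s0, e0 = placed
            stage = embryo_stages[len(ddmr_rows) % len(embryo_stages)]
            ddmr_rows.append(
                {
                    "chrom": chrom,
                    "start": s0,
                    "end": e0,
                    "stage": stage,
                    "direction": "hyper",
                    "host_gene": genes.iloc[g].gene_id,
                    "host_class": genes.iloc[g].gene_class,
                    "location": "promoter",
                    "module_id": f"M{mid + 1}",
                }
            )

    n_rest = config.n_ddmr - len(ddmr_rows)
    n_prom = int(round(n_rest * 2 / 3))
    for j in range(n_rest):
        where = "promoter" if j < n_prom else "body"
        if where == "promoter":
            cls = "lncRNA" if j < round(0.64 * n_prom) else "coding"
        else:
            cls = "lncRNA" if j % 2 == 0 else "coding"
        for _ in range(10):
            g = take_host(cls)
            placed = planner.place(genes.iloc[g], where)
            if placed:
                break
        else:
            raise ConfigError(f"could not place planted D-DMR {j}")
        chrom, s0, e0 = placed
        stage = embryo_stages[len(ddmr_rows) % len(embryo_stages)]
        direction = "hypo" if j % 4 == 3 else "hyper"
        ddmr_rows.append(
            {
                "chrom": chrom,
                "start": s0,
                "end": e0,
                "stage": stage,
                "direction": direction,
                "host_gene": genes.iloc[g].gene_id,
                "host_class": cls,
                "location": where,
                "module_id": "",
            }
        )

    gdmrs = pd.DataFrame(
        gdmr_rows,
        columns=["chrom", "start", "end", "gamete", "host_gene", "host_class", "location"],
    )
    ddmrs = pd.DataFrame(
        ddmr_rows,
        columns=[
            "chrom",
            "start",
            "end",
            "stage",
            "direction",
            "host_gene",
            "host_class",
            "location",
            "module_id",
        ],
    )
    modules = pd.DataFrame(module_rows, columns=["module_id", "gene_id", "is_seed"])

    # ---- regional stage means at every CpG ------------------------------
    mean_by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in annotation.cpg_positions.items():
        M = np.repeat(base[:, None], len(pos), axis=1)
        sub = genes[genes.chrom == chrom]
        for r in sub.itertuples():
            i0, i1 = np.searchsorted(pos, [r.start, r.end])
            M[:, i0:i1] = base[:, None] * body_mult[r.Index]
        # promoters keep a residual methylation floor through the wave:
        # per-gene propensity persists even at the 2-cell nadir
        prom_base = PROMOTER_FLOOR + (1.0 - PROMOTER_FLOOR) * base
        for r in sub.itertuples():
            j0, j1 = np.searchsorted(pos, [r.promoter_start, r.promoter_end])
            M[:, j0:j1] = prom_base[:, None] * prom_mult[r.Index]
        cgi = annotation.features["cgi"]
        for r in cgi[cgi.chrom == chrom].itertuples():
            k0, k1 = np.searchsorted(pos, [r.start, r.end])
            M[:, k0:k1] *= 0.3
        for r in gdmrs[gdmrs.chrom == chrom].itertuples():
            k0, k1 = np.searchsorted(pos, [r.start, r.end])
            M[:, k0:k1] = _gdmr_trajectory(stages, r.gamete)[:, None]
        for r in ddmrs[ddmrs.chrom == chrom].itertuples():
            k0, k1 = np.searchsorted(pos, [r.start, r.end])
            M[:, k0:k1] = _ddmr_trajectory(stages, r.stage, r.direction)[:, None]
        mean_by_chrom[chrom] = np.clip(M, 0.01, 0.99)

    for df, kind in ((gdmrs, "G-DMR"), (ddmrs, "D-DMR")):
        for r in df.itertuples():
            pos = annotation.cpg_positions[r.chrom]
            if np.searchsorted(pos, r.end) - np.searchsorted(pos, r.start) < 1:
                raise ConfigError(f"planted {kind} at {r.chrom}:{r.start} has no CpG")

    # ---- true regional means per gene (for the expression model) --------
    prom_meth = np.empty((len(genes), S))
    body_meth = np.empty((len(genes), S))
    for r in genes.itertuples():
        pos = annotation.cpg_positions[r.chrom]
        M = mean_by_chrom[r.chrom]
        j0, j1 = np.searchsorted(pos, [r.promoter_start, r.promoter_end])
        prom_fallback = (PROMOTER_FLOOR + (1.0 - PROMOTER_FLOOR) * base) * prom_mult[r.Index]
        prom_meth[r.Index] = M[:, j0:j1].mean(axis=1) if j1 > j0 else prom_fallback
        # gene body excluding the promoter window, so promoter and body
        # signals stay statistically separable
        if r.strand == "+":
            b0, b1 = min(r.tss + 1000, r.end), r.end
        else:
            b0, b1 = r.start, max(r.tss - 1000, r.start)
        i0, i1 = np.searchsorted(pos, [b0, b1])
        body_meth[r.Index] = (
            M[:, i0:i1].mean(axis=1) if i1 > i0 else base * body_mult[r.Index]
        )
    prom_df = pd.DataFrame(prom_meth, index=genes.gene_id, columns=list(stages))
    body_df = pd.DataFrame(body_meth, index=genes.gene_id, columns=list(stages))

    # ---- draw counts -----------------------------------------------------
    kappa = 1.0 / config.beta_dispersion
    samples: list[CpGCounts] = []
    sample_to_stage: dict[str, str] = {}
    for si, stage in enumerate(stages):
        for rep in range(config.replicates_per_stage):
            sid = f"{stage}_r{rep + 1}"
            sample_to_stage[sid] = stage
            frames = []
            for chrom in annotation.chrom_sizes:
                pos = annotation.cpg_positions[chrom]
                m = mean_by_chrom[chrom][si]
                cov = np.maximum(rng.poisson(config.coverage_mean, len(pos)), 1)
                p = rng.beta(m * kappa, (1.0 - m) * kappa)
                meth = rng.binomial(cov, p)
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": pos,
                            "count_meth": meth,
                            "count_unmeth": cov - meth,
                        }
                    )
                )
            samples.append(CpGCounts(sample_id=sid, df=pd.concat(frames, ignore_index=True)))

    coupling = pd.DataFrame(
        {
            "gene_id": genes.gene_id,
            "promoter_slope": config.coupling_slope,
            "body_slope": config.gene_body_slope,
        }
    )
    truth = GroundTruth(
        gdmrs=gdmrs,
        ddmrs=ddmrs,
        modules=modules,
        coupling=coupling,
        promoter_meth=prom_df,
        body_meth=body_df,
        sample_to_stage=sample_to_stage,
    )
    return samples, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    annotation: GenomeAnnotation, truth: GroundTruth, config: SimulationConfig
) -> ExpressionMatrix:
    """FPKM-like matrix with planted methylation coupling and modules.

    log2 expression = baseline + coupling_slope * promoter methylation
    + gene_body_slope * gene-body methylation + module factor + noise;
    FPKM = 2**log2expr, hence strictly positive.
    """
    rng = np.random.default_rng([config.seed, 3])
    genes = annotation.genes
    stages = config.stages
    n_genes = len(genes)

    sample_ids, sample_stages = [], []
    for stage in stages:
        for c in range(config.cells_per_stage):
            sample_ids.append(f"{stage}_c{c + 1}")
            sample_stages.append(stage)
    n_samples = len(sample_ids)

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_genes)
    stage_idx = np.array([list(stages).index(s) for s in sample_stages])
    P = truth.promoter_meth.to_numpy()[:, stage_idx]  # genes x samples
    B = truth.body_meth.to_numpy()[:, stage_idx]
    logexpr = (
        baseline[:, None]
        + config.coupling_slope * P
        + config.gene_body_slope * B
        + rng.normal(0.0, config.expr_noise_sd, (n_genes, n_samples))
    )
    gene_pos = {g: i for i, g in enumerate(genes.gene_id)}
    for mid, grp in truth.modules.groupby("module_id"):
        f = rng.normal(0.0, 1.0, n_samples)
        rows = [gene_pos[g] for g in grp.gene_id]
        logexpr[rows] += config.module_strength * f[None, :]

    fpkm = np.exp2(logexpr)
    df = pd.DataFrame(fpkm, index=pd.Index(genes.gene_id, name="gene_id"), columns=sample_ids)
    return ExpressionMatrix(df=df, sample_to_stage=dict(zip(sample_ids, sample_stages)))


def simulate_dataset(config: SimulationConfig) -> FixtureDataset:
    """One-call convenience: annotation + methylomes + expression + truth."""
    annotation = generate_annotation(config)
    samples, truth = simulate_methylomes(annotation, config)
    expression = simulate_expression(annotation, truth, config)
    return FixtureDataset(
        config=config,
        annotation=annotation,
        samples=samples,
        truth=truth,
        expression=expression,
    )


# ---------------------------------------------------------------------------
# fixture writer
# ---------------------------------------------------------------------------


def _write_gtf(genes: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        for r in genes.itertuples():
            attrs = (
                f'gene_id "{r.gene_id}"; transcript_id "{r.gene_id}.1"; '
                f'gene_biotype "{r.gene_class}";'
            )
            for feat, a, b in (
                ("gene", r.start, r.end),
                ("transcript", r.start, r.end),
            ):
                fh.write(
                    f"{r.chrom}\tpedmeth\t{feat}\t{a + 1}\t{b}\t.\t{r.strand}\t.\t{attrs}\n"
                )
            es = [int(x) for x in r.exon_starts.split(",")]
            ee = [int(x) for x in r.exon_ends.split(",")]
            for a, b in zip(es, ee):
                fh.write(
                    f"{r.chrom}\tpedmeth\texon\t{a + 1}\t{b}\t.\t{r.strand}\t.\t{attrs}\n"
                )


def _write_bed12(genes: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        for r in genes.itertuples():
            es = [int(x) for x in r.exon_starts.split(",")]
            ee = [int(x) for x in r.exon_ends.split(",")]
            sizes = ",".join(str(b - a) for a, b in zip(es, ee)) + ","
            offs = ",".join(str(a - r.start) for a in es) + ","
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\t0\t{r.strand}\t"
                f"{r.start}\t{r.end}\t0\t{len(es)}\t{sizes}\t{offs}\n"
            )


def write_fixture(dataset: FixtureDataset, out_dir: str | Path) -> Path:
    """Serialize a fixture to plain-text files.

    Layout: coverage/<sample>.cov (Bismark coverage, 1-based inclusive),
    annotation/ (GTF, BED12, feature BED3s), expression/ (FPKM TSV + sample
    map), truth/ (planted tables), manifest.json.
    """
    out = Path(out_dir)
    for sub in ("coverage", "annotation", "expression", "truth"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    for s in dataset.samples:
        path = out / "coverage" / f"{s.sample_id}.cov"
        with open(path, "w") as fh:
            for r in s.df.itertuples():
                tot = r.count_meth + r.count_unmeth
                pct = 100.0 * r.count_meth / tot
                fh.write(
                    f"{r.chrom}\t{r.pos + 1}\t{r.pos + 1}\t{pct:.6f}\t"
                    f"{r.count_meth}\t{r.count_unmeth}\n"
                )

    ann = dataset.annotation
    _write_gtf(ann.genes, out / "annotation" / "genes.gtf")
    _write_bed12(ann.genes, out / "annotation" / "genes.bed")
    for name in ("cgi", "exon", "intron"):
        ann.features[name].to_csv(
            out / "annotation" / f"{name}.bed", sep="\t", header=False, index=False
        )

    dataset.expression.df.to_csv(out / "expression" / "expression.tsv", sep="\t")
    pd.Series(dataset.expression.sample_to_stage, name="stage").rename_axis(
        "sample"
    ).to_csv(out / "expression" / "samples.tsv", sep="\t")

    t = dataset.truth
    t.gdmrs.to_csv(out / "truth" / "gdmrs.tsv", sep="\t", index=False)
    t.ddmrs.to_csv(out / "truth" / "ddmrs.tsv", sep="\t", index=False)
    t.modules.to_csv(out / "truth" / "modules.tsv", sep="\t", index=False)
    t.coupling.to_csv(out / "truth" / "coupling.tsv", sep="\t", index=False)
    t.promoter_meth.to_csv(out / "truth" / "promoter_methylation.tsv", sep="\t")
    t.body_meth.to_csv(out / "truth" / "body_methylation.tsv", sep="\t")
    pd.Series(t.sample_to_stage, name="stage").rename_axis("sample").to_csv(
        out / "truth" / "sample_stages.tsv", sep="\t"
    )

    manifest = {
        "config": dataset.config.to_dict(),
        "seed": dataset.config.seed,
        "n_samples": len(dataset.samples),
        "n_genes": len(ann.genes),
        "n_cpgs": int(sum(len(p) for p in ann.cpg_positions.values())),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
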