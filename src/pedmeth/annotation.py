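"""Gene models, promoters, feature assignment, TSS meta-profiles.

A gene model carries a single TSS (the 5' end respecting strand; transcripts
are collapsed to the longest isoform) and a promoter defined as 1 kb up- and
downstream of the TSS, i.e. a fixed 2,000-bp window. Tiles are assigned to
promoter/exon/intron/CGI features by >= 1 bp overlap (multi-label).
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParseError
from .quant import StageMethylome, TileMethylome

log = logging.getLogger(__name__)

PROMOTER_FLANK = 1000

GENE_COLUMNS = [
    "gene_id",
    "gene_class",
    "chrom",
    "strand",
    "start",
    "end",
    "tss",
    "promoter_start",
    "promoter_end",
    "exon_starts",
    "exon_ends",
]


def _finish_gene_table(rows: list[dict]) -> pd.DataFrame:
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    bad = ~genes["strand"].isin(["+", "-"])
    if bad.any():
        ids = ", ".join(genes.loc[bad, "gene_id"])
        raise DataError(f"unknown strand for gene(s): {ids}")
    return genes.sort_values(["chrom", "start", "gene_id"], kind="mergesort").reset_index(
        drop=True
    )


def _load_gtf(path: Path, class_label: str | None) -> pd.DataFrame:
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    rows = []
    for gene in db.features_of_type("gene"):
        transcripts = list(db.children(gene, featuretype="transcript"))
        if transcripts:
            tx = max(transcripts, key=lambda t: t.end - t.start)
            exons = list(db.children(tx, featuretype="exon", order_by="start"))
        else:  # gene with bare exon children
            tx = gene
            exons = list(db.children(gene, featuretype="exon", order_by="start"))
        start, end = tx.start - 1, tx.end  # GTF is 1-based inclusive
        if not exons:
            exon_starts, exon_ends = [start], [end]
        else:
            exon_starts = [e.start - 1 for e in exons]
            exon_ends = [e.end for e in exons]
        tss = start if gene.strand == "+" else end
        cls = gene.attributes.get("gene_biotype", [class_label])[0]
        rows.append(
            {
                "gene_id": gene.id,
                "gene_class": cls,
                "chrom": gene.seqid,
                "strand": gene.strand,
                "start": start,
                "end": end,
                "tss": tss,
                "promoter_start": tss - PROMOTER_FLANK,
                "promoter_end": tss + PROMOTER_FLANK,
                "exon_starts": ",".join(map(str, exon_starts)),
                "exon_ends": ",".join(map(str, exon_ends)),
            }
        )
    return _finish_gene_table(rows)


def _load_bed12(path: Path, class_label: str | None) -> pd.DataFrame:
    names = [
        "chrom",
        "start",
        "end",
        "name",
        "score",
        "strand",
        "thick_start",
        "thick_end",
        "rgb",
        "block_count",
        "block_sizes",
        "block_starts",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=names, dtype={"chrom": str})
    if df["name"].duplicated().any():
        dup = df.loc[df["name"].duplicated(), "name"].iloc[0]
        raise ParseError(f"{path}: duplicated gene id {dup}")
    rows = []
    for r in df.itertuples():
        sizes = [int(x) for x in str(r.block_sizes).rstrip(",").split(",")]
        offs = [int(x) for x in str(r.block_starts).rstrip(",").split(",")]
        exon_starts = [r.start + o for o in offs]
        exon_ends = [a + s for a, s in zip(exon_starts, sizes)]
        tss = r.start if r.strand == "+" else r.end
        rows.append(
            {
                "gene_id": r.name,
                "gene_class": class_label,
                "chrom": r.chrom,
                "strand": r.strand,
                "start": int(r.start),
                "end": int(r.end),
                "tss": int(tss),
                "promoter_start": int(tss) - PROMOTER_FLANK,
                "promoter_end": int(tss) + PROMOTER_FLANK,
                "exon_starts": ",".join(map(str, exon_starts)),
                "exon_ends": ",".join(map(str, exon_ends)),
            }
        )
    return _finish_gene_table(rows)


def load_genes(path: str | Path, class_label: str | None = None) -> pd.DataFrame:
    """Load gene models from GTF or BED12 into the canonical gene table.

    GTF gene_biotype attributes override class_label when present. Internal
    coordinates are 0-based half-open; TSS respects strand and the promoter
    is TSS +/- 1 kb.
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff", ".gff3"):
        return _load_gtf(path, class_label)
    return _load_bed12(path, class_label)


def filter_distal_lncrna(
    lncrnas: pd.DataFrame, codings: pd.DataFrame, min_dist: int = 1000
) -> pd.DataFrame:
    """Keep lncRNAs whose gene body is >= min_dist bp from every coding body.

    Used to exclude lncRNAs nested in or abutting protein-coding genes when
    comparing TSS profiles between the classes. Chromosomes with no coding
    gene retain all their lncRNAs.
    """
    keep = []
    by_chrom = {c: g for c, g in codings.groupby("chrom")}
    for r in lncrnas.itertuples():
        sub = by_chrom.get(r.chrom)
        if sub is None or sub.empty:
            keep.append(True)
            continue
        gap = np.maximum(sub["start"].to_numpy() - r.end, r.start - sub["end"].to_numpy())
        keep.append(bool(np.all(gap >= min_dist)))
    return lncrnas.loc[keep].reset_index(drop=True)


def gene_body_regions(genes: pd.DataFrame, exclude_promoter: bool = True) -> pd.DataFrame:
    """Per-gene body regions for region-level methylation.

    With exclude_promoter the TSS +/- 1 kb promoter window is removed from
    the body (it sits at the 5' end), keeping promoter and gene-body signals
    separable; genes whose body is entirely promoter come back empty
    (start == end) and will be reported missing downstream.
    """
    out = genes[["gene_id", "chrom", "start", "end"]].rename(
        columns={"gene_id": "region_id"}
    ).copy()
    if exclude_promoter:
        plus = genes["strand"] == "+"
        out.loc[plus, "start"] = np.minimum(
            genes.loc[plus, "tss"] + PROMOTER_FLANK, genes.loc[plus, "end"]
        )
        out.loc[~plus, "end"] = np.maximum(
            genes.loc[~plus, "tss"] - PROMOTER_FLANK, genes.loc[~plus, "start"]
        )
    return out


def assign_tiles(
    tiles: pd.DataFrame, features: dict[str, pd.DataFrame], tile_size: int = 100
) -> pd.DataFrame:
    """Multi-label tiles by >= 1 bp overlap with each named feature set.

    Tiles must sit on the fixed [k*tile_size, (k+1)*tile_size) grid, so
    overlap reduces to integer arithmetic on tile indices. Adds one boolean
    column per feature plus 'intergenic' (no promoter/exon/intron overlap).
    """
    out = tiles[["chrom", "start", "end"]].copy().reset_index(drop=True)
    tile_key = pd.Series(
        list(zip(out["chrom"], out["start"] // tile_size)), index=out.index
    )
    for name, fdf in features.items():
        hit: set[tuple[str, int]] = set()
        for r in fdf.itertuples():
            if r.end <= r.start:
                continue
            first = max(r.start // tile_size, 0)
            last = (r.end - 1) // tile_size
            hit.update((r.chrom, k) for k in range(first, last + 1))
        out[name] = tile_key.isin(hit).to_numpy()
    genic = [c for c in ("promoter", "exon", "intron") if c in out.columns]
    if genic:
        out["intergenic"] = ~out[genic].any(axis=1)
    return out


def region_methylation(
    methylome: TileMethylome | StageMethylome,
    regions: pd.DataFrame,
    tile_size: int = 100,
) -> pd.Series:
    """Mean retained-tile level per region; NaN where no tile is covered.

    A region's level is the unweighted mean of the levels of retained tiles
    overlapping it by >= 1 bp; regions without any retained tile are missing
    (NaN), never 0.
    """
    mdf = methylome.df
    level_by_tile: dict[tuple[str, int], float] = {
        (c, s // tile_size): lv
        for c, s, lv in zip(mdf["chrom"], mdf["start"], mdf["level"])
    }
    vals = []
    for r in regions.itertuples():
        if r.end <= r.start:
            vals.append(np.nan)
            continue
        first = max(r.start // tile_size, 0)
        last = (r.end - 1) // tile_size
        levels = [
            level_by_tile[(r.chrom, k)]
            for k in range(first, last + 1)
            if (r.chrom, k) in level_by_tile
        ]
        vals.append(float(np.mean(levels)) if levels else np.nan)
    index = regions["region_id"] if "region_id" in regions.columns else regions.index
    return pd.Series(vals, index=index, name="level")


def tss_profile(
    methylome: TileMethylome | StageMethylome | pd.DataFrame,
    genes: pd.DataFrame,
    flank: int = 5000,
    window: int = 100,
    value_col: str = "level",
) -> pd.DataFrame:
    """Strand-oriented meta-profile of tile values around gene TSSs.

    Tiles are binned by the offset of their midpoint from the TSS into
    contiguous windows; minus-strand genes are flipped so +x is downstream.
    Per-bin values are first averaged within a gene, then across genes.
    Returns (offset_bp, mean, n) with offset_bp the bin's left edge and n
    the number of genes contributing.
    """
    if genes.empty:
        raise DataError("tss_profile requires at least one gene")
    mdf = methylome if isinstance(methylome, pd.DataFrame) else methylome.df
    by_chrom = {
        c: (g["start"].to_numpy() + (g["end"] - g["start"]).to_numpy() / 2.0,
            g[value_col].to_numpy())
        for c, g in mdf.sort_values(["chrom", "start"]).groupby("chrom")
    }
    recs = []
    for r in genes.itertuples():
        if r.chrom not in by_chrom:
            continue
        mids, vals = by_chrom[r.chrom]
        i0, i1 = np.searchsorted(mids, [r.tss - flank, r.tss + flank])
        if i1 <= i0:
            continue
        off = mids[i0:i1] - r.tss
        if r.strand == "-":
            off = -off
        bins = np.floor(off / window).astype(int)
        inside = (bins >= -flank // window) & (bins < flank // window)
        for b, v in zip(bins[inside], vals[i0:i1][inside]):
            recs.append((r.gene_id, b, v))
    if not recs:
        return pd.DataFrame(columns=["offset_bp", "mean", "n"])
    df = pd.DataFrame(recs, columns=["gene_id", "bin", "value"])
    per_gene = df.groupby(["gene_id", "bin"])["value"].mean().reset_index()
    prof = per_gene.groupby("bin")["value"].agg(["mean", "size"]).reset_index()
    prof["offset_bp"] = prof["bin"] * window
    return prof.rename(columns={"size": "n"})[["offset_bp", "mean", "n"]]


def ks_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test with asymptotic p."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DataError("ks_compare requires >= 2 values in each sample")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)
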