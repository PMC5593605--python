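"""Per-CpG and 100-bp-tile methylation quantification from bisulfite counts.

The methylation level of a CpG is M / (M + U): reads reporting C over reads
reporting C or T. Single-CpG levels are restricted to CpGs with coverage
>= min_cov (default 5x). For 100-bp tiles, counts of every sufficiently
covered CpG inside the tile are pooled and the tile level is the pooled
ratio; a tile is retained iff at least one CpG contributes. The level of a
stage is the arithmetic mean of its biological replicates over tiles covered
in every replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, ParseError

log = logging.getLogger(__name__)

COVERAGE_COLUMNS = ["chrom", "start", "end", "percent", "count_meth", "count_unmeth"]


@dataclass
class CpGCounts:
    """Per-sample methylated/unmethylated read counts at CpG cytosines.

    Positions are 0-based, unique per chromosome, sorted by (chrom, pos).
    """

    sample_id: str
    df: pd.DataFrame  # chrom, pos, count_meth, count_unmeth


@dataclass
class TileMethylome:
    sample_id: str
    df: pd.DataFrame  # chrom, start, end, level, pooled_meth, pooled_total,
    #                   cpg_density, n_cpgs_used


@dataclass
class StageMethylome:
    stage: str
    df: pd.DataFrame  # chrom, start, end, level
    n_replicates: int


def load_coverage(path: str | Path, sample_id: str | None = None) -> CpGCounts:
    """Read a 6-column Bismark coverage file into 0-based CpGCounts.

    File coordinates are 1-based inclusive; internal positions are the
    0-based cytosine position. Malformed lines raise ParseError with the
    line number; duplicated positions raise ParseError naming the position.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=COVERAGE_COLUMNS,
            dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=COVERAGE_COLUMNS)
    if df.empty:
        log.warning("coverage file %s is empty", path)
        return CpGCounts(
            sample_id=sample_id,
            df=pd.DataFrame(columns=["chrom", "pos", "count_meth", "count_unmeth"]),
        )
    if df.shape[1] != 6:
        raise ParseError(f"{path}: expected 6 tab-separated columns")
    for col in ("start", "end", "count_meth", "count_unmeth"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round()) | (vals < 0)
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ParseError(
                f"{path} line {line}: column {col!r} must be a nonnegative integer"
            )
        df[col] = vals.astype(np.int64)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"] - 1,
            "count_meth": df["count_meth"],
            "count_unmeth": df["count_unmeth"],
        }
    )
    dup = out.duplicated(subset=["chrom", "pos"])
    if dup.any():
        r = out[dup].iloc[0]
        raise ParseError(f"{path}: duplicated CpG position {r.chrom}:{r.pos + 1}")
    out = out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return CpGCounts(sample_id=sample_id, df=out)


def cpg_methylation(counts: CpGCounts, min_cov: int = 5) -> pd.DataFrame:
    """Per-CpG levels M/(M+U) for CpGs with coverage >= min_cov."""
    if min_cov < 1:
        raise ConfigError("min_cov must be >= 1")
    df = counts.df
    cov = df["count_meth"] + df["count_unmeth"]
    keep = cov >= min_cov
    out = df.loc[keep, ["chrom", "pos"]].copy()
    out["level"] = (df.loc[keep, "count_meth"] / cov[keep]).astype(float)
    return out.reset_index(drop=True)


def cpg_density(
    positions: np.ndarray, query_pos: int | np.ndarray, window: int = 50
) -> int | np.ndarray:
    """CpG density: number of CpG sites within +/- window bp of a CpG.

    The query site counts itself; positions must be the sorted CpG positions
    of one chromosome and the query must be one of them.
    """
    positions = np.asarray(positions)
    q = np.atleast_1d(np.asarray(query_pos))
    idx = np.searchsorted(positions, q)
    known = (idx < len(positions)) & (positions[np.minimum(idx, len(positions) - 1)] == q)
    if not known.all():
        raise ValueError(f"query position {q[~known][0]} is not a known CpG site")
    lo = np.searchsorted(positions, q - window, side="left")
    hi = np.searchsorted(positions, q + window, side="right")
    dens = (hi - lo).astype(int)
    return int(dens[0]) if np.isscalar(query_pos) or np.ndim(query_pos) == 0 else dens


def tile_methylation(
    counts: CpGCounts,
    tile_size: int = 100,
    min_cov: int = 5,
    density_window: int = 50,
) -> TileMethylome:
    """Pool covered CpGs into fixed [k*tile_size, (k+1)*tile_size) tiles.

    Only CpGs with coverage >= min_cov contribute; the tile level is the
    pooled ratio (equal to the coverage-weighted mean of per-CpG levels).
    Tile CpG density is the mean single-CpG density of contributing CpGs,
    where density counts all CpGs in the file within +/- density_window bp.
    """
    if min_cov < 1:
        raise ConfigError("min_cov must be >= 1")
    df = counts.df.reset_index(drop=True)
    if df.empty:
        return TileMethylome(
            sample_id=counts.sample_id,
            df=pd.DataFrame(
                columns=[
                    "chrom",
                    "start",
                    "end",
                    "level",
                    "pooled_meth",
                    "pooled_total",
                    "cpg_density",
                    "n_cpgs_used",
                ]
            ),
        )
    dens = np.empty(len(df), dtype=int)
    for chrom, grp in df.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        dens[grp.index] = cpg_density(pos, pos, window=density_window)
    cov = (df["count_meth"] + df["count_unmeth"]).to_numpy()
    keep = cov >= min_cov
    sub = df.loc[keep].copy()
    sub["density"] = dens[keep]
    sub["cov"] = cov[keep]
    sub["tile"] = sub["pos"] // tile_size
    g = sub.groupby(["chrom", "tile"], sort=True)
    out = g.agg(
        pooled_meth=("count_meth", "sum"),
        pooled_total=("cov", "sum"),
        cpg_density=("density", "mean"),
        n_cpgs_used=("pos", "size"),
    ).reset_index()
    out["start"] = out["tile"] * tile_size
    out["end"] = out["start"] + tile_size
    out["level"] = out["pooled_meth"] / out["pooled_total"]
    out = out[
        [
            "chrom",
            "start",
            "end",
            "level",
            "pooled_meth",
            "pooled_total",
            "cpg_density",
            "n_cpgs_used",
        ]
    ]
    return TileMethylome(sample_id=counts.sample_id, df=out)


def stage_average(
    replicates: list[TileMethylome], stage: str | None = None
) -> StageMethylome:
    """Arithmetic mean of replicate tile levels over tiles covered in all.

    The tile set is the intersection of the replicate tile sets; levels are
    averaged unweighted (replicates are not weighted by coverage).
    """
    if not replicates:
        raise ConfigError("stage_average requires at least one replicate")
    if stage is None:
        stage = replicates[0].sample_id
    n = len(replicates)
    cat = pd.concat(
        [r.df[["chrom", "start", "end", "level"]] for r in replicates],
        ignore_index=True,
    )
    g = cat.groupby(["chrom", "start", "end"], sort=True)["level"].agg(["mean", "size"])
    g = g[g["size"] == n]
    out = g.reset_index().rename(columns={"mean": "level"})[
        ["chrom", "start", "end", "level"]
    ]
    return StageMethylome(stage=stage, df=out, n_replicates=n)


def sample_mean_level(methylome: TileMethylome | StageMethylome) -> float:
    """Genome-wide methylation of a sample: unweighted mean over its tiles."""
    if methylome.df.empty:
        raise ValueError("methylome has no retained tiles")
    return float(methylome.df["level"].mean())


def status_fractions(
    levels, low: float = 0.20, high: float = 0.80
) -> tuple[float, float, float]:
    """Fractions of tiles with low (<low), intermediate, and high (>high) levels.

    Values exactly at the boundaries count as intermediate.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValueError("status_fractions requires a nonempty level vector")
    n = levels.size
    frac_low = float(np.sum(levels < low)) / n
    frac_high = float(np.sum(levels > high)) / n
    return frac_low, 1.0 - frac_low - frac_high, frac_high
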