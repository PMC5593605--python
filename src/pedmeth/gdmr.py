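"""Gamete-specific DMR calling, trajectory clustering, and enrichment.

A 100-bp tile covered in both sperm and oocyte is a gamete-specific DMR
(G-DMR) when its mean level exceeds 0.75 in one gamete and falls below 0.25
in the other, and a per-tile two-sample Student's t-test across biological
replicates survives Benjamini-Hochberg FDR < 0.05. With two replicates per
gamete the t-test has two degrees of freedom and the level thresholds carry
most of the selection; that is the documented behaviour, not a defect.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError
from .quant import StageMethylome, TileMethylome

log = logging.getLogger(__name__)

TILE_KEY = ["chrom", "start", "end"]


def _level_matrix(replicates: list[TileMethylome]) -> pd.DataFrame:
    """Tiles x replicates level matrix over tiles covered in all replicates."""
    frames = [
        r.df.set_index(TILE_KEY)["level"].rename(r.sample_id) for r in replicates
    ]
    return pd.concat(frames, axis=1, join="inner")


def _cpg_tile_stats(
    cpg_levels: list[pd.DataFrame], tile_size: int
) -> pd.DataFrame:
    """Per-tile n, mean, var of pooled (CpG, replicate) level observations."""
    cat = pd.concat(cpg_levels, ignore_index=True)
    cat["tile"] = cat["pos"] // tile_size
    g = cat.groupby(["chrom", "tile"])["level"]
    out = g.agg(n="size", mean="mean", var="var")
    out["var"] = out["var"].fillna(0.0)
    return out


def _pooled_t(sa: pd.DataFrame, sb: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    n1, n2 = sa["n"].to_numpy(), sb["n"].to_numpy()
    m1, m2 = sa["mean"].to_numpy(), sb["mean"].to_numpy()
    v1, v2 = sa["var"].to_numpy(), sb["var"].to_numpy()
    df = n1 + n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        t = (m1 - m2) / np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
        p = 2.0 * stats.t.sf(np.abs(t), df=df)
    # both groups constant: identical means -> no evidence; distinct -> certain
    bad = ~np.isfinite(t)
    p = np.where(bad, np.where(m1 == m2, 1.0, 0.0), p)
    t = np.where(bad, np.where(m1 == m2, 0.0, np.inf * np.sign(m1 - m2 + 1e-300)), t)
    return t, p


def call_gdmrs(
    sperm_reps: list[TileMethylome],
    oocyte_reps: list[TileMethylome],
    hi: float = 0.75,
    lo: float = 0.25,
    fdr: float = 0.05,
    method: str = "cpg",
    sperm_cpg: list[pd.DataFrame] | None = None,
    oocyte_cpg: list[pd.DataFrame] | None = None,
    tile_size: int = 100,
) -> pd.DataFrame:
    """Call G-DMRs on tiles covered in every sperm and oocyte replicate.

    The threshold rule always acts on replicate-level tile means. The
    t-test unit is configurable: method='cpg' (default) treats every
    (CpG, replicate) level inside the tile as an observation — pass the
    per-replicate per-CpG level tables (from cpg_methylation) as
    sperm_cpg/oocyte_cpg; method='replicates' tests the replicate tile
    means, which with two replicates per gamete has only two degrees of
    freedom and little power after FDR correction. Returns tiles passing
    both the threshold rule and BH q < fdr.
    """
    if hi <= lo:
        raise ConfigError(f"hi ({hi}) must exceed lo ({lo})")
    if len(sperm_reps) < 2 or len(oocyte_reps) < 2:
        raise ConfigError("call_gdmrs requires >= 2 replicates per gamete")
    sp = _level_matrix(sperm_reps)
    oo = _level_matrix(oocyte_reps)
    common = sp.index.intersection(oo.index)
    if common.empty:
        raise DataError("no tiles covered in both gametes")
    A = sp.loc[common].to_numpy()
    B = oo.loc[common].to_numpy()
    mean_s, mean_o = A.mean(axis=1), B.mean(axis=1)
    if method == "replicates":
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_ind(A, B, axis=1, equal_var=True)
        degenerate = np.isnan(p)
        p = np.where(degenerate, np.where(mean_s == mean_o, 1.0, 0.0), p)
        t = np.where(np.isnan(t), np.where(mean_s == mean_o, 0.0, np.inf), t)
    elif method == "cpg":
        if sperm_cpg is None or oocyte_cpg is None:
            raise ConfigError(
                "method='cpg' requires per-CpG level tables (sperm_cpg, oocyte_cpg)"
            )
        key = pd.DataFrame(
            {"chrom": common.get_level_values(0),
             "tile": common.get_level_values(1) // tile_size}
        )
        idx = pd.MultiIndex.from_frame(key)
        sa = _cpg_tile_stats(sperm_cpg, tile_size).reindex(idx)
        sb = _cpg_tile_stats(oocyte_cpg, tile_size).reindex(idx)
        if sa["n"].isna().any() or sb["n"].isna().any():
            raise DataError("per-CpG tables do not cover every tested tile")
        t, p = _pooled_t(sa, sb)
    else:
        raise ConfigError(f"unknown t-test method {method!r}")
    q = multipletests(p, method="fdr_bh")[1]

    sperm_specific = (mean_s > hi) & (mean_o < lo)
    oocyte_specific = (mean_o > hi) & (mean_s < lo)
    called = (sperm_specific | oocyte_specific) & (q < fdr)
    out = pd.DataFrame(index=common[called]).reset_index()
    out.columns = TILE_KEY
    out["gamete"] = np.where(sperm_specific[called], "sperm", "oocyte")
    out["mean_sperm"] = mean_s[called]
    out["mean_oocyte"] = mean_o[called]
    out["t"] = t[called]
    out["p"] = p[called]
    out["q"] = q[called]
    return out.sort_values(TILE_KEY, kind="mergesort").reset_index(drop=True)


def dmr_stage_matrix(
    dmrs: pd.DataFrame, stage_methylomes: list[StageMethylome]
) -> pd.DataFrame:
    """DMRs x stages level matrix from stage-averaged methylomes (NaN = uncovered)."""
    idx = pd.MultiIndex.from_frame(dmrs[TILE_KEY])
    cols = {}
    for sm in stage_methylomes:
        s = sm.df.set_index(TILE_KEY)["level"]
        cols[sm.stage] = s.reindex(idx).to_numpy()
    return pd.DataFrame(cols, index=idx)


def cluster_dynamics(
    matrix: pd.DataFrame, k: int = 6, seed: int = 0
) -> tuple[np.ndarray, pd.DataFrame]:
    """k-means on per-DMR stage trajectories, deterministic for a seed.

    Missing stage values are imputed with the stage mean over all DMRs.
    Cluster ids 1..k are assigned in decreasing cluster-size order and the
    centroid table is returned in the same order.
    """
    if k < 2:
        raise ConfigError("k must be >= 2")
    if len(matrix) < k:
        raise DataError(f"{len(matrix)} DMRs is fewer than k={k} clusters")
    X = matrix.to_numpy(dtype=float).copy()
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    sizes = np.bincount(km.labels_, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    assignments = relabel[km.labels_]
    centroids = pd.DataFrame(
        km.cluster_centers_[order],
        index=pd.Index(np.arange(1, k + 1), name="cluster_id"),
        columns=matrix.columns,
    )
    return assignments, centroids


def annotation_enrichment(
    universe: pd.DataFrame,
    dmr_mask: np.ndarray,
    labels: list[str],
    fdr_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Hypergeometric enrichment of a DMR set in tile annotation labels.

    universe is a tile table with one boolean column per label (as produced
    by assign_tiles); dmr_mask flags the DMR tiles within it. For each label
    the upper-tail p is P(X >= k) with X ~ Hypergeom(N=|universe|,
    K=#labeled, n=#DMRs); BH is applied across labels.
    """
    N = len(universe)
    if N == 0:
        raise DataError("empty tile universe")
    dmr_mask = np.asarray(dmr_mask, dtype=bool)
    n = int(dmr_mask.sum())
    rows = []
    for label in labels:
        lab = universe[label].to_numpy(dtype=bool)
        K = int(lab.sum())
        k = int((lab & dmr_mask).sum())
        expected = n * K / N
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"label": label, "overlap": k, "set_size": K, "n_dmrs": n,
             "universe": N, "expected": expected, "p": p}
        )
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method=fdr_method)[1] if len(out) else []
    return out


def assign_dmrs_to_genes(
    dmrs: pd.DataFrame, genes: pd.DataFrame, region: str = "body"
) -> pd.DataFrame:
    """Host-gene assignment by >= 1 bp overlap with gene bodies or promoters.

    A DMR overlapping genes of both classes appears once per class and is
    flagged ambiguous. Returns (DMR tile, gene_id, gene_class, ambiguous).
    """
    if region == "body":
        gs, ge = genes["start"].to_numpy(), genes["end"].to_numpy()
    elif region == "promoter":
        gs, ge = genes["promoter_start"].to_numpy(), genes["promoter_end"].to_numpy()
    else:
        raise ConfigError(f"unknown region {region!r}")
    rows = []
    for r in dmrs.itertuples():
        hit = (genes["chrom"].to_numpy() == r.chrom) & (gs < r.end) & (ge > r.start)
        sub = genes.loc[hit]
        ambiguous = sub["gene_class"].nunique() > 1
        for g in sub.itertuples():
            rows.append(
                {
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "gamete": getattr(r, "gamete", None),
                    "gene_id": g.gene_id,
                    "gene_class": g.gene_class,
                    "ambiguous": ambiguous,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "gamete", "gene_id", "gene_class", "ambiguous"],
    )


def parental_bias(assigned: pd.DataFrame) -> dict:
    """Per-class sperm/oocyte fractions with a Pearson chi-square test.

    assigned is the output of assign_dmrs_to_genes for called G-DMRs; each
    (DMR, class) pair counts once. Returns per-class fractions, the 2x2
    contingency table (class x gamete), chi2 and p (no continuity
    correction).
    """
    if assigned.empty:
        raise DataError("no gene-assigned DMRs for parental bias")
    tab = (
        assigned.drop_duplicates(["chrom", "start", "end", "gamete", "gene_class"])
        .groupby(["gene_class", "gamete"])
        .size()
        .unstack(fill_value=0)
        .reindex(index=["lncRNA", "coding"], columns=["sperm", "oocyte"], fill_value=0)
    )
    if (tab.sum(axis=1) == 0).any():
        raise DataError("a gene class has no assigned DMRs")
    frac = (tab["sperm"] / tab.sum(axis=1)).to_dict()
    chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
    return {
        "table": tab,
        "sperm_fraction": frac,
        "oocyte_fraction": {k: 1.0 - v for k, v in frac.items()},
        "chi2": float(chi2),
        "p": float(p),
    }
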