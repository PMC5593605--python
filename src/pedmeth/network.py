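"""Coding-noncoding co-expression network and gene-set enrichment.

Pipeline: filter genes by expression (max FPKM > 5 and variance in the top
75% of genes), compute all-pairs Pearson correlation on log2(FPKM + 1)
across expression samples, attach a p-value from Fisher's asymptotic test
(t = r * sqrt(n - 2) / sqrt(1 - r^2) referred to a t distribution with
n - 2 df, two-sided), and keep pairs with |r| > 0.8, p < 0.05 and at least
one endpoint among the seed genes (genes with a promoter D-DMR). Gene-set
enrichment of network members is an upper-tail hypergeometric test with BH
correction per term family.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError
from .expression import ExpressionMatrix

log = logging.getLogger(__name__)


def filter_genes(
    expr: ExpressionMatrix,
    min_max_expr: float = 5.0,
    var_keep_fraction: float = 0.75,
    log2: bool = True,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Expressed, variable genes: max FPKM > min_max_expr and variance in
    the top var_keep_fraction of all genes.

    Variance is computed on log2(FPKM + 1) when log2 is set. Setting
    var_keep_fraction = 0.25 selects only the top quartile instead of the
    top three quartiles. Returns the filtered genes x samples matrix.
    """
    if expr.df.empty:
        raise DataError("empty expression matrix")
    if not 0 < var_keep_fraction <= 1:
        raise ConfigError("var_keep_fraction must be in (0, 1]")
    X = np.log2(expr.df + pseudocount) if log2 else expr.df
    max_ok = expr.df.max(axis=1) > min_max_expr
    variances = X.var(axis=1, ddof=1)
    cut = variances.quantile(1.0 - var_keep_fraction)
    keep = max_ok & (variances >= cut)
    if not keep.any():
        raise DataError(
            "no gene survives filtering; lower min_max_expr or raise "
            "var_keep_fraction"
        )
    return X.loc[keep]


def fisher_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a Pearson r under Fisher's asymptotic test.

    t = r * sqrt(n - 2) / sqrt(1 - r^2) with n - 2 degrees of freedom;
    |r| = 1 maps to p = 0 without overflow.
    """
    if n < 4:
        raise DataError("Fisher's asymptotic test needs >= 4 samples")
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.isclose(np.abs(r), 1.0), 0.0, p)


def pcc_and_fisher(expr_subset: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Pearson r and Fisher-asymptotic p on a genes x samples matrix.

    Pairs involving a constant gene are reported with NaN r and p (missing).
    Rows come back with gene_a < gene_b lexicographically.
    """
    genes = expr_subset.index.to_numpy()
    X = expr_subset.to_numpy(dtype=float)
    n = X.shape[1]
    if n < 4:
        raise DataError("pcc_and_fisher needs >= 4 samples")
    sd = X.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.corrcoef(X)
    R[sd == 0, :] = np.nan
    R[:, sd == 0] = np.nan
    iu, ju = np.triu_indices(len(genes), k=1)
    r = R[iu, ju]
    p = np.full_like(r, np.nan)
    ok = ~np.isnan(r)
    p[ok] = fisher_pvalue(r[ok], n)
    a, b = genes[iu], genes[ju]
    swap = a > b
    a, b = np.where(swap, b, a), np.where(swap, a, b)
    return pd.DataFrame({"gene_a": a, "gene_b": b, "r": r, "p": p, "n": n})


def build_network(
    pairs: pd.DataFrame,
    seed_genes,
    r_min: float = 0.8,
    p_max: float = 0.05,
    gene_classes: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain pairs with |r| > r_min, p < p_max and >= 1 seeded endpoint.

    seed_genes are the promoter-D-DMR genes the network is anchored on.
    Returns (edges, nodes); nodes carry gene class and seed flag.
    """
    seed = set(seed_genes)
    if not seed:
        raise ConfigError("seed_genes must be nonempty")
    ok = (
        (pairs["r"].abs() > r_min)
        & (pairs["p"] < p_max)
        & (pairs["gene_a"].isin(seed) | pairs["gene_b"].isin(seed))
        & pairs["r"].notna()
    )
    edges = pairs.loc[ok].reset_index(drop=True).copy()
    edges["seed_flag"] = True
    if edges.empty:
        log.warning("no edge survives |r| > %s and p < %s gates", r_min, p_max)
    node_ids = sorted(set(edges["gene_a"]) | set(edges["gene_b"]))
    classes = gene_classes or {}
    nodes = pd.DataFrame(
        {
            "gene_id": node_ids,
            "gene_class": [classes.get(g, "unknown") for g in node_ids],
            "is_seed": [g in seed for g in node_ids],
        }
    )
    return edges, nodes


def to_graph(edges: pd.DataFrame, nodes: pd.DataFrame | None = None) -> nx.Graph:
    g = nx.Graph()
    if nodes is not None:
        for r in nodes.itertuples():
            g.add_node(r.gene_id, gene_class=r.gene_class, is_seed=bool(r.is_seed))
    for r in edges.itertuples():
        g.add_edge(r.gene_a, r.gene_b, r=float(r.r), p=float(r.p))
    return g


def topology(graph: nx.Graph, hub_quantile: float = 0.05) -> dict:
    """Degrees, hubs (top hub_quantile by degree), and component sizes."""
    if graph.number_of_nodes() == 0:
        return {
            "degrees": pd.Series(dtype=int),
            "hubs": [],
            "component_sizes": [],
            "n_nodes": 0,
            "n_edges": 0,
        }
    degrees = pd.Series(dict(graph.degree())).sort_values(ascending=False)
    n_hubs = max(1, int(np.ceil(hub_quantile * len(degrees))))
    cutoff = degrees.iloc[n_hubs - 1]
    hubs = list(degrees[degrees >= cutoff].index)
    comps = sorted((len(c) for c in nx.connected_components(graph)), reverse=True)
    return {
        "degrees": degrees,
        "hubs": hubs,
        "component_sizes": comps,
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
    }


def geneset_enrichment(
    query_genes,
    term_to_genes: pd.DataFrame,
    universe,
    fdr_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a query in gene-set terms.

    term_to_genes is a two-column (term, gene) table; the universe is the
    background gene list the query was drawn from. Per term: k = |query n
    term|, K = |term n universe|, n = |query|, N = |universe|;
    p = P(X >= k), fold = (k/n) / (K/N); BH across terms. Terms with K = 0
    are skipped (logged).
    """
    universe = set(universe)
    query = set(query_genes)
    if not query <= universe:
        raise DataError("query genes must be a subset of the universe")
    if term_to_genes.empty:
        raise DataError("empty term table")
    N, n = len(universe), len(query)
    rows = []
    term_col, gene_col = term_to_genes.columns[:2]
    for term, grp in term_to_genes.groupby(term_col, sort=True):
        members = set(grp[gene_col]) & universe
        K = len(members)
        if K == 0:
            log.info("term %s has no genes in the universe; skipped", term)
            continue
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n else np.nan
        rows.append(
            {"term": term, "overlap": k, "set_size": K, "query_size": n,
             "universe": N, "fold_enrichment": fold, "p": p}
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = multipletests(out["p"], method=fdr_method)[1]
    return out
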