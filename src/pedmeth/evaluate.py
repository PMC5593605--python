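"""Scoring of called structure against the generator's ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd


def _region_tiles(regions: pd.DataFrame, tile_size: int = 100) -> set[tuple[str, int]]:
    tiles: set[tuple[str, int]] = set()
    for r in regions.itertuples():
        for k in range(r.start // tile_size, (r.end - 1) // tile_size + 1):
            tiles.add((r.chrom, k))
    return tiles


def gdmr_recovery(
    called: pd.DataFrame, truth: pd.DataFrame, tile_size: int = 100
) -> dict:
    """Sensitivity/precision of G-DMR calls against planted regions.

    A planted region is recovered when >= 1 called tile of the matching
    gamete overlaps it; a called tile is correct when it overlaps a planted
    region of its gamete.
    """
    out = {"n_called": len(called), "n_planted": len(truth)}
    rec = 0
    for r in truth.itertuples():
        hit = called[
            (called["gamete"] == r.gamete)
            & (called["chrom"] == r.chrom)
            & (called["start"] < r.end)
            & (called["end"] > r.start)
        ]
        rec += int(len(hit) > 0)
    out["sensitivity"] = rec / len(truth) if len(truth) else np.nan
    correct = 0
    by_gamete = {g: _region_tiles(t, tile_size) for g, t in truth.groupby("gamete")}
    for r in called.itertuples():
        correct += int((r.chrom, r.start // tile_size) in by_gamete.get(r.gamete, set()))
    out["precision"] = correct / len(called) if len(called) else np.nan
    return out


def ddmr_recovery(
    called: pd.DataFrame,
    truth: pd.DataFrame,
    n_tested: int,
    tile_size: int = 100,
    exclude: pd.DataFrame | None = None,
) -> dict:
    """Sensitivity and constant-background false-call rate of D-DMR calls.

    false_call_rate = called tiles outside every planted region, over the
    number of tested background tiles (tested tiles minus planted tiles).
    `exclude` lists regions that are planted structure of another kind
    (e.g. gamete-specific DMRs, which genuinely vary across stages); calls
    there count neither as false calls nor as background.
    """
    out = {"n_called": len(called), "n_planted": len(truth), "n_tested": n_tested}
    excl_tiles = _region_tiles(exclude, tile_size) if exclude is not None else set()
    rec = 0
    for r in truth.itertuples():
        hit = called[
            (called["chrom"] == r.chrom)
            & (called["start"] < r.end)
            & (called["end"] > r.start)
        ]
        rec += int(len(hit) > 0)
    out["sensitivity"] = rec / len(truth) if len(truth) else np.nan
    planted = _region_tiles(truth, tile_size)
    false_calls = sum(
        1
        for r in called.itertuples()
        if (r.chrom, r.start // tile_size) not in planted
        and (r.chrom, r.start // tile_size) not in excl_tiles
    )
    n_background = max(n_tested - len(planted) - len(excl_tiles), 1)
    out["n_false_calls"] = false_calls
    out["false_call_rate"] = false_calls / n_background
    return out


def module_edge_precision(edges: pd.DataFrame, modules: pd.DataFrame) -> dict:
    """Fraction of retained network edges that are within-module pairs."""
    gene_module = dict(zip(modules["gene_id"], modules["module_id"]))
    if edges.empty:
        return {"n_edges": 0, "n_within_module": 0, "precision": np.nan}
    within = sum(
        1
        for r in edges.itertuples()
        if gene_module.get(r.gene_a) is not None
        and gene_module.get(r.gene_a) == gene_module.get(r.gene_b)
    )
    return {
        "n_edges": len(edges),
        "n_within_module": within,
        "precision": within / len(edges),
    }
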