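"""Expression matrix handling and methylation-expression correlation.

Expression is an FPKM genes x samples matrix with a sample -> stage map.
Per stage, expression is averaged over that stage's cells, transformed as
log2(FPKM + 1), and correlated (Pearson) against per-gene regional
methylation (promoter or gene body) across genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParseError

log = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    df: pd.DataFrame  # genes x samples, FPKM >= 0, index = gene_id
    sample_to_stage: dict[str, str]

    @property
    def stages(self) -> list[str]:
        seen: list[str] = []
        for s in self.df.columns:
            st = self.sample_to_stage[s]
            if st not in seen:
                seen.append(st)
        return seen

    def stage_means(self, log2: bool = True, pseudocount: float = 1.0) -> pd.DataFrame:
        """Genes x stages matrix of per-stage mean expression.

        FPKM is averaged over each stage's samples and then, by default,
        log2(mean + pseudocount)-transformed.
        """
        stage_of = pd.Series({s: self.sample_to_stage[s] for s in self.df.columns})
        means = self.df.T.groupby(stage_of).mean().T
        means = means[self.stages]
        if log2:
            means = np.log2(means + pseudocount)
        return means


def load_expression(
    path: str | Path, sample_map: dict[str, str]
) -> ExpressionMatrix:
    """Parse a genes x samples FPKM TSV with a header row of sample ids."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicated gene id {dup}")
    if (df.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative expression value")
    missing = [s for s in df.columns if s not in sample_map]
    if missing:
        raise DataError(f"samples missing from the stage map: {', '.join(missing)}")
    df.index.name = "gene_id"
    return ExpressionMatrix(df=df, sample_to_stage={s: sample_map[s] for s in df.columns})


def methylation_expression_correlation(
    region_levels: pd.DataFrame,
    expr: ExpressionMatrix,
    min_genes: int = 3,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-stage Pearson r between regional methylation and expression.

    region_levels is a genes x stages table of methylation levels (promoter
    or gene-body), indexed by gene_id; stages must match the expression
    stage labels. r is computed across genes within each stage on
    (methylation level, log2(stage-mean FPKM + 1)); stages where either
    vector is constant, or with fewer than min_genes complete genes, are
    reported with NaN r and a reason.
    """
    em = expr.stage_means(log2=True, pseudocount=pseudocount)
    shared_genes = region_levels.index.intersection(em.index)
    rows = []
    for stage in em.columns:
        if stage not in region_levels.columns:
            rows.append({"stage": stage, "r": np.nan, "p": np.nan, "n": 0,
                         "reason": "no methylation for stage"})
            continue
        m = region_levels.loc[shared_genes, stage]
        e = em.loc[shared_genes, stage]
        ok = m.notna() & e.notna()
        n = int(ok.sum())
        if n < min_genes:
            rows.append({"stage": stage, "r": np.nan, "p": np.nan, "n": n,
                         "reason": f"fewer than {min_genes} genes"})
            continue
        mv, ev = m[ok].to_numpy(), e[ok].to_numpy()
        if np.ptp(mv) == 0 or np.ptp(ev) == 0:
            rows.append({"stage": stage, "r": np.nan, "p": np.nan, "n": n,
                         "reason": "constant vector"})
            continue
        r, p = stats.pearsonr(mv, ev)
        rows.append({"stage": stage, "r": float(r), "p": float(p), "n": n, "reason": ""})
    return pd.DataFrame(rows, columns=["stage", "r", "p", "n", "reason"])
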