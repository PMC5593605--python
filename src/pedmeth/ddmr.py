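"""Developmental-specific DMRs via Shannon entropy of stage profiles.

A tile's stage methylation vector m is normalized to a pseudo-probability
distribution p_s = (m_s + eps) / sum(m_t + eps) and scored by
H = -sum p_s log2 p_s. A tile methylated in essentially one stage
concentrates p and has low entropy; a flat profile is maximally entropic
(log2 S bits) regardless of its absolute level. Specificity through
HYPOmethylation inverts this picture, so the entropy is also computed on
the reflected vector m'_s = (max m + min m) - m_s and the minimum of the
two orientations is reported, with the minimizing orientation recorded as
the direction. Tiles below an entropy threshold are called D-DMRs; the
reference threshold 4.22 bits belongs to a 32-sample design (range log2 32
= 5 bits) and is rescaled to log2(S) * 4.22 / 5 for other sample counts.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .quant import StageMethylome

log = logging.getLogger(__name__)

REFERENCE_THRESHOLD = 4.22  # bits, defined for S = 32 samples
REFERENCE_SAMPLES = 32


def _entropy_bits(m: np.ndarray, epsilon: float) -> np.ndarray:
    p = (m + epsilon) / (m + epsilon).sum(axis=-1, keepdims=True)
    return -(p * np.log2(p)).sum(axis=-1)


def methylation_entropy(
    m, epsilon: float = 1e-3, return_direction: bool = False
):
    """Orientation-minimized Shannon entropy (bits) of a stage vector.

    Accepts a single vector or a (tiles x stages) matrix. Direction is
    'hyper' when the raw orientation minimizes H (specificity through a
    methylation peak) and 'hypo' when the reflected orientation does.
    """
    m = np.asarray(m, dtype=float)
    single = m.ndim == 1
    M = np.atleast_2d(m)
    if M.shape[1] < 2:
        raise DataError("entropy requires at least 2 stages")
    if np.any((M < 0) | (M > 1)):
        raise DataError("methylation levels must lie in [0, 1]")
    h_raw = _entropy_bits(M, epsilon)
    refl = (M.max(axis=1, keepdims=True) + M.min(axis=1, keepdims=True)) - M
    h_ref = _entropy_bits(refl, epsilon)
    H = np.minimum(h_raw, h_ref)
    direction = np.where(h_raw <= h_ref, "hyper", "hypo")
    if single:
        H, direction = float(H[0]), str(direction[0])
    if return_direction:
        return H, direction
    return H


def scaled_threshold(n_samples: int, reference: float = REFERENCE_THRESHOLD) -> float:
    """Rescale the reference entropy threshold to another sample count."""
    if n_samples < 2:
        raise ConfigError("need >= 2 samples for an entropy threshold")
    if n_samples == REFERENCE_SAMPLES:
        return reference
    t = reference * math.log2(n_samples) / math.log2(REFERENCE_SAMPLES)
    log.warning(
        "entropy threshold rescaled to %.3f bits for %d samples "
        "(reference %.2f at %d samples)",
        t,
        n_samples,
        reference,
        REFERENCE_SAMPLES,
    )
    return t


def call_ddmrs(
    stage_methylomes: list[StageMethylome],
    threshold: float | None = None,
    epsilon: float = 1e-3,
) -> pd.DataFrame:
    """Call D-DMRs on tiles covered in every stage.

    Tiles missing in any stage are excluded (count logged). Returns the
    called tiles with their stage levels, entropy H, direction, and the
    threshold used.
    """
    if len(stage_methylomes) < 2:
        raise ConfigError("call_ddmrs requires >= 2 stages")
    S = len(stage_methylomes)
    if threshold is None:
        threshold = scaled_threshold(S)
    if threshold >= math.log2(S):
        log.warning(
            "threshold %.3f >= log2(S)=%.3f: every covered tile can be called",
            threshold,
            math.log2(S),
        )
    frames = [
        sm.df.set_index(["chrom", "start", "end"])["level"].rename(sm.stage)
        for sm in stage_methylomes
    ]
    full = pd.concat(frames, axis=1)
    n_dropped = int(full.isna().any(axis=1).sum())
    if n_dropped:
        log.info("excluded %d tiles missing in >= 1 stage", n_dropped)
    full = full.dropna()
    if full.empty:
        return full.reset_index().assign(H=[], direction=[])
    H, direction = methylation_entropy(
        full.to_numpy(), epsilon=epsilon, return_direction=True
    )
    out = full.reset_index()
    out["H"] = H
    out["direction"] = direction
    called = out[out["H"] < threshold].reset_index(drop=True)
    called.attrs["threshold"] = threshold
    called.attrs["n_tested"] = len(full)
    called.attrs["n_dropped"] = n_dropped
    return called


def ddmr_class_summary(
    assigned_body: pd.DataFrame, assigned_promoter: pd.DataFrame
) -> dict:
    """Class composition of D-DMR host genes, body and promoter separately.

    Inputs are assign_dmrs_to_genes outputs for the called D-DMRs. For each
    compartment, reports the fraction of (DMR, class) assignments per gene
    class and a Pearson chi-square comparing class composition between the
    two compartments. Empty inputs yield an empty summary without a test.
    """
    out: dict = {}
    counts = {}
    for name, assigned in (("body", assigned_body), ("promoter", assigned_promoter)):
        if assigned.empty:
            out[name] = {"n": 0, "class_fraction": {}}
            counts[name] = None
            continue
        uniq = assigned.drop_duplicates(["chrom", "start", "end", "gene_class"])
        by_cls = uniq.groupby("gene_class").size()
        by_cls = by_cls.reindex(["lncRNA", "coding"], fill_value=0)
        out[name] = {
            "n": int(by_cls.sum()),
            "class_fraction": (by_cls / by_cls.sum()).to_dict(),
            "n_genes": int(assigned["gene_id"].nunique()),
        }
        counts[name] = by_cls
    if counts["body"] is not None and counts["promoter"] is not None:
        tab = np.vstack([counts["body"].to_numpy(), counts["promoter"].to_numpy()])
        if (tab.sum(axis=1) > 0).all() and (tab.sum(axis=0) > 0).all():
            chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
            out["chi2"], out["p"] = float(chi2), float(p)
    return out
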