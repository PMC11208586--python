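"""Coupling of per-gene contact changes (delta EP#) to nascent-transcription
fold changes, and the candidate-gene selection funnel.

Two correlation paths are provided, mirroring how such studies report them:
the outlier-robust grouped resampling (genes grouped by delta EP#, repeated
fixed-size draws, Pearson on group grand means) and the direct Pearson on
raw per-gene (delta EP#, log FC) pairs for a small candidate list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ResampleResult:
    """Outcome of the grouped resampling correlation.

    ``groups`` has one row per delta EP# group: the group value, member
    count, whether draws used replacement, and the grand mean of the
    per-draw mean log fold-changes.  ``draw_means`` maps group value to the
    vector of per-draw means.
    """

    groups: pd.DataFrame
    draw_means: dict[int, np.ndarray]
    pearson_r: float
    p_value: float
    group_size: int
    reps: int
    seed: int


def group_resample_logfc(ep_table: pd.DataFrame,
                         log_fc: Mapping[str, float] | pd.Series,
                         group_size: int = 70, reps: int = 200,
                         seed: int = 0) -> ResampleResult:
    """Resampling correlation between delta EP# groups and mean log FC.

    Genes are partitioned by their ``delta_ep`` value.  From each group,
    ``group_size`` genes are drawn ``reps`` times -- without replacement
    when the group has at least ``group_size`` members, with replacement
    otherwise (so sparse tails are kept rather than dropped) -- and each
    draw's mean log fold-change is recorded.  Pearson r and its two-sided
    p are computed between group delta EP# values and the grand means.
    """
    lf = pd.Series(log_fc)
    missing = [g for g in ep_table["gene_id"] if g not in lf.index]
    if missing:
        raise KeyError(f"no log_fc for genes {missing[:5]}"
                       + ("..." if len(missing) > 5 else ""))
    rng = np.random.default_rng(seed)
    rows = []
    draw_means: dict[int, np.ndarray] = {}
    for delta, sub in sorted(ep_table.groupby("delta_ep"),
                             key=lambda kv: kv[0]):
        vals = lf.loc[sub["gene_id"]].to_numpy(float)
        replace = len(vals) < group_size
        means = np.empty(reps)
        for i in range(reps):
            idx = rng.choice(len(vals), size=group_size, replace=replace)
            means[i] = vals[idx].mean()
        draw_means[int(delta)] = means
        rows.append({"delta_ep": int(delta), "n_genes": len(vals),
                     "with_replacement": replace,
                     "grand_mean_log_fc": means.mean()})
    groups = pd.DataFrame(rows)
    if len(groups) < 2:
        raise ValueError("need >= 2 distinct delta_ep groups for correlation")
    r, p = stats.pearsonr(groups["delta_ep"], groups["grand_mean_log_fc"])
    return ResampleResult(groups, draw_means, float(r), float(p),
                          group_size, reps, seed)


def correlate_candidates(delta_ep: Sequence[float],
                         log_fc: Sequence[float]) -> tuple[float, float]:
    """Pearson r and two-sided p (t transform, n-2 df) on raw gene pairs."""
    x = np.asarray(delta_ep, float)
    y = np.asarray(log_fc, float)
    if x.size != y.size:
        raise ValueError("delta_ep and log_fc lengths differ")
    if x.size < 3:
        raise ValueError("need at least 3 pairs for a correlation p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one coordinate; r undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class CandidateGeneSet:
    """Stage sets of the selection funnel.

    Invariant: ``enhanced_contacts`` (when set) is a subset of
    ``intersection``, which is a subset of ``up_in_senescence``.
    """

    up_in_senescence: frozenset[str]
    down_on_mettl3_kd: frozenset[str]
    down_on_mettl14_kd: frozenset[str]
    intersection: frozenset[str]
    mode: str = "both"
    enhanced_contacts: frozenset[str] | None = None
    pairs: pd.DataFrame | None = None   # gene_id, delta_ep, log_fc

    def __post_init__(self):
        if not self.intersection <= self.up_in_senescence:
            raise ValueError("intersection not within up-in-senescence set")
        if (self.enhanced_contacts is not None
                and not self.enhanced_contacts <= self.intersection):
            raise ValueError("enhanced-contact set not within intersection")


CONTRAST_SEN = "sen_vs_growing"
CONTRAST_M3 = "shMETTL3_vs_sen"
CONTRAST_M14 = "shMETTL14_vs_sen"


def select_mtc_dependent_genes(expression: pd.DataFrame,
                               up_lfc: float = 1.0, down_lfc: float = 1.0,
                               alpha: float = 0.05,
                               mode: str = "both") -> CandidateGeneSet:
    """Genes up in senescence and down on methyltransferase knockdown.

    ``up`` = log_fc >= up_lfc and padj < alpha in the senescence contrast;
    the knockdown ``down`` sets use log_fc <= -down_lfc.  ``mode="both"``
    intersects both knockdowns (Venn-overlap reading); ``mode="either"``
    requires only one.
    """
    if mode not in ("both", "either"):
        raise ValueError(f"unknown mode {mode!r}")

    def _sel(contrast: str, sign: int, thr: float) -> frozenset[str]:
        sub = expression[expression["contrast"] == contrast]
        if sub.empty:
            raise KeyError(f"contrast {contrast!r} missing from expression table")
        if sign > 0:
            keep = (sub["log_fc"] >= thr) & (sub["padj"] < alpha)
        else:
            keep = (sub["log_fc"] <= -thr) & (sub["padj"] < alpha)
        return frozenset(sub.loc[keep, "gene_id"])

    up = _sel(CONTRAST_SEN, +1, up_lfc)
    d3 = _sel(CONTRAST_M3, -1, down_lfc)
    d14 = _sel(CONTRAST_M14, -1, down_lfc)
    kd = (d3 & d14) if mode == "both" else (d3 | d14)
    return CandidateGeneSet(up, d3, d14, frozenset(up & kd), mode=mode)


def intersect_enhanced_contacts(candidates: CandidateGeneSet,
                                ep_table: pd.DataFrame,
                                log_fc: Mapping[str, float] | pd.Series,
                                ) -> CandidateGeneSet:
    """Restrict candidates to genes with strictly enhanced contacts.

    Keeps genes with delta_ep > 0 and attaches (delta_ep, log_fc) pairs
    for the downstream candidate correlation.
    """
    delta = ep_table.set_index("gene_id")["delta_ep"]
    missing = [g for g in candidates.intersection if g not in delta.index]
    if missing:
        raise KeyError(f"delta_ep missing for candidates {missing[:5]}")
    lf = pd.Series(log_fc)
    kept = frozenset(g for g in candidates.intersection if delta[g] > 0)
    pairs = pd.DataFrame({
        "gene_id": sorted(kept),
        "delta_ep": [int(delta[g]) for g in sorted(kept)],
        "log_fc": [float(lf[g]) for g in sorted(kept)],
    })
    return CandidateGeneSet(
        candidates.up_in_senescence, candidates.down_on_mettl3_kd,
        candidates.down_on_mettl14_kd, candidates.intersection,
        mode=candidates.mode, enhanced_contacts=kept, pairs=pairs)
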