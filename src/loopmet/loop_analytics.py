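"""Loop significance filtering, distance classes, enhancer-promoter (EP)
assignment and counting, and contact-matrix balancing.

The EP logic follows the HiChIP convention used in senescence chromatin
studies: a significant loop is an EP interaction if either anchor overlaps
a promoter window (TSS +/- 1 kb) by at least one base, and EP# is the
per-gene count of such loops in a condition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genomic_io import GeneCatalog, GenomicInterval, Loop

logger = logging.getLogger(__name__)

#: per-assay significance rule: (FDR threshold, minimum read count)
# H3K27Ac HiChIP: FDR < 0.01 with at least 4 reads; METTL3 HiChIP: FDR < 0.05
# with no read floor.
SIGNIFICANCE_RULES: dict[str, tuple[float, int]] = {
    "H3K27Ac": (0.01, 4),
    "METTL3": (0.05, 0),
}

SHORT_MAX = 5_000        # short-distance: < 5 kb
MEDIUM_MAX = 2_000_000   # medium-distance: 5 kb - 2 Mb (closed); long: > 2 Mb

DISTANCE_CLASSES = ("short", "medium", "long", "trans")


def filter_significant_loops(loops: Sequence[Loop], assay: str,
                             fdr: float | None = None,
                             min_reads: int | None = None) -> list[Loop]:
    """Keep loops passing the assay's significance rule.

    H3K27Ac: FDR < 0.01 and read_count >= 4.  METTL3: FDR < 0.05 (no read
    floor).  Both thresholds can be overridden.
    """
    if assay not in SIGNIFICANCE_RULES:
        raise ValueError(f"unknown assay {assay!r}; "
                         f"known: {sorted(SIGNIFICANCE_RULES)}")
    rule_fdr, rule_reads = SIGNIFICANCE_RULES[assay]
    fdr = rule_fdr if fdr is None else fdr
    min_reads = rule_reads if min_reads is None else min_reads
    for lp in loops:
        if lp.assay != assay:
            raise ValueError(f"loop with assay {lp.assay!r} passed to "
                             f"filter for {assay!r}")
    return [lp for lp in loops if lp.fdr < fdr and lp.read_count >= min_reads]


def classify_distance(loop: Loop) -> str:
    """Distance class of a loop by anchor-midpoint separation.

    short: d < 5 kb; medium: 5 kb <= d <= 2 Mb; long: d > 2 Mb;
    inter-chromosomal loops are ``trans``.
    """
    if not loop.is_intra:
        return "trans"
    d = loop.span
    if d < SHORT_MAX:
        return "short"
    if d <= MEDIUM_MAX:
        return "medium"
    return "long"


def distance_distribution(loops: Sequence[Loop]) -> pd.DataFrame:
    """Counts and percentages per distance class.

    Returns a frame indexed by class with ``count`` and ``pct`` columns;
    classes partition the input exactly and percentages sum to 100.
    """
    counts = {c: 0 for c in DISTANCE_CLASSES}
    for lp in loops:
        counts[classify_distance(lp)] += 1
    total = sum(counts.values())
    if total == 0:
        warnings.warn("distance_distribution called on an empty loop set")
        pct = {c: 0.0 for c in DISTANCE_CLASSES}
    else:
        pct = {c: 100.0 * n / total for c, n in counts.items()}
    return pd.DataFrame({"count": pd.Series(counts), "pct": pd.Series(pct)})


@dataclass(frozen=True)
class PromoterWindow:
    """The promoter of a gene: TSS +/- flank, clipped at the chromosome start."""

    gene_id: str
    interval: GenomicInterval


def define_promoters(catalog: GeneCatalog, flank: int = 1000) -> list[PromoterWindow]:
    """One symmetric window [tss - flank, tss + flank) per gene.

    The window is strand-independent and clipped at position 0.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    out = []
    for g in catalog:
        start = max(0, g.tss - flank)
        out.append(PromoterWindow(
            g.gene_id, GenomicInterval(g.chrom, start, g.tss + flank)))
    return out


def _promoter_trees(promoters: Iterable[PromoterWindow]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for pw in promoters:
        trees.setdefault(pw.interval.chrom, IntervalTree()).addi(
            pw.interval.start, pw.interval.end, pw.gene_id)
    return trees


def assign_ep(loops: Sequence[Loop],
              promoters: Sequence[PromoterWindow]) -> list[frozenset[str]]:
    """For each loop, the set of genes whose promoter either anchor touches.

    Overlap is half-open, >= 1 bp.  A loop with both anchors in promoters
    of different genes is attributed to both; an empty set means the loop
    is not an EP interaction.  The result is aligned with the input order.
    """
    trees = _promoter_trees(promoters)
    out = []
    for lp in loops:
        genes: set[str] = set()
        for anchor in (lp.anchor_a, lp.anchor_b):
            tree = trees.get(anchor.chrom)
            if tree is not None:
                genes.update(iv.data for iv in tree.overlap(anchor.start,
                                                            anchor.end))
        out.append(frozenset(genes))
    return out


def count_ep_per_gene(assignments_by_condition: Mapping[str, Sequence[frozenset[str]]],
                      catalog: GeneCatalog,
                      growing: str = "growing",
                      senescent: str = "senescent",
                      sign: str = "senescent_minus_growing") -> pd.DataFrame:
    """Per-gene EP# by condition and the signed difference ``delta_ep``.

    A loop counts once per (loop, gene) even if both anchors hit the same
    gene's promoter.  The default sign convention makes contact gain in
    senescence positive; ``sign="growing_minus_senescent"`` matches the
    opposite printed order.
    """
    for cond in (growing, senescent):
        if cond not in assignments_by_condition:
            raise KeyError(f"condition {cond!r} absent from assignments")
    counts = {cond: {g: 0 for g in catalog.gene_ids}
              for cond in (growing, senescent)}
    for cond in (growing, senescent):
        for genes in assignments_by_condition[cond]:
            for gid in genes:
                if gid in counts[cond]:
                    counts[cond][gid] += 1
    df = pd.DataFrame({
        "gene_id": catalog.gene_ids,
        "ep_growing": [counts[growing][g] for g in catalog.gene_ids],
        "ep_senescent": [counts[senescent][g] for g in catalog.gene_ids],
    })
    if sign == "senescent_minus_growing":
        df["delta_ep"] = df["ep_senescent"] - df["ep_growing"]
    elif sign == "growing_minus_senescent":
        df["delta_ep"] = df["ep_growing"] - df["ep_senescent"]
    else:
        raise ValueError(f"unknown sign convention {sign!r}")
    return df


@dataclass
class ContactMatrix:
    """A symmetric binned contact map (default 10-kb bins)."""

    values: np.ndarray
    bin_size: int = 10_000
    chrom: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("contact matrix must be square")

    def check_valid(self, tol: float = 1e-8) -> None:
        if np.any(self.values < 0):
            raise ValueError("contact matrix has negative entries")
        if not np.allclose(self.values, self.values.T, atol=tol, rtol=tol):
            raise ValueError("contact matrix not symmetric within tolerance")


def ice_balance(matrix: ContactMatrix, iterations: int = 30,
                tol: float | None = None) -> ContactMatrix:
    """Iterative correction (ICE) of a contact matrix.

    Each round divides the matrix by the outer product of row-sum bias
    estimates renormalized to mean 1; rows/columns with zero marginals are
    excluded and stay exactly zero.  After the fixed number of rounds
    (30 by default) the total mass is rescaled to the input mass.  An
    optional ``tol`` stops early once the nonzero row-sum coefficient of
    variation drops below it.
    """
    matrix.check_valid()
    M = matrix.values.copy()
    mass_in = M.sum()
    nz = M.sum(axis=1) > 0
    if not nz.any():
        warnings.warn("all-zero contact matrix; returned unchanged")
        return ContactMatrix(M, matrix.bin_size, matrix.chrom)
    for _ in range(iterations):
        s = M.sum(axis=1)
        bias = np.ones_like(s)
        bias[nz] = s[nz] / s[nz].mean()
        M /= np.outer(bias, bias)
        if tol is not None:
            s = M.sum(axis=1)[nz]
            if s.std() / s.mean() < tol:
                break
    # conserve total mass
    M *= mass_in / M.sum()
    return ContactMatrix(M, matrix.bin_size, matrix.chrom)


def cap_top_quantile(matrix: ContactMatrix, q: float = 0.05) -> ContactMatrix:
    """Cap values above the (1-q) quantile of nonzero entries (display scaling).

    With the default q=0.05 the maximum displayed intensity corresponds to
    the top-5% score.  Idempotent; an all-zero matrix is returned unchanged
    with a warning.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    M = matrix.values.copy()
    nonzero = M[M > 0]
    if nonzero.size == 0:
        warnings.warn("cap_top_quantile on an all-zero matrix")
        return ContactMatrix(M, matrix.bin_size, matrix.chrom)
    # "lower" picks an actual order statistic, which makes capping idempotent
    cap = float(np.quantile(nonzero, 1 - q, method="lower"))
    np.minimum(M, cap, out=M)
    return ContactMatrix(M, matrix.bin_size, matrix.chrom)
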