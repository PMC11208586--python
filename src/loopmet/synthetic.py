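"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here, scaled to about
one tenth of a real senescence study (500 genes, ~2,000 loops, ~50
polymethylated transcripts, a 5-arm tracing panel) so the full test suite
runs in well under a minute.  Each generator is a pure function of its
config (seed included): identical configs give identical outputs, and the
planted truth round-trips exactly through the matching pipeline stage at
zero noise.

What is emulated: two-condition loop sets with planted per-gene EP counts;
expression log fold-changes linearly coupled to delta EP# plus Gaussian
noise; knockdown contrasts that reverse a planted gene subset; planted
per-transcript m6A site counts with a polymethylated+downregulated funnel;
isotopologue vectors built by convolving planted MIDs with binomial
natural 13C abundance plus lognormal multiplicative noise; Ct tables with
Gaussian cycle noise.  What is not: read-level data, real genome sequence,
mapping artifacts, dispersion structure of real count data.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import (GeneCatalog, GeneModel, GenomicInterval, Loop,
                         write_gene_models_gtf, write_loops, write_table)
from .loop_analytics import define_promoters
from .tracing import (ALL_GROUPS, DEFAULT_P13C, GROUP_CONTROL, GROUP_MUT,
                      GROUP_SEN, GROUP_SHHK2, GROUP_WT,
                      natural_abundance_matrix)


@dataclass(frozen=True)
class MetaboliteSpec:
    """Planted labeled fractions for one metabolite across the five groups."""

    name: str
    n_carbons: int
    m_label: int                      # isotopologue index screened (e.g. M+5)
    fractions: Mapping[str, float]    # group -> labeled fraction
    expected_pass: bool               # planted screen outcome


def _default_panel() -> tuple[MetaboliteSpec, ...]:
    # effect sizes ~10x the intensity noise (sigma 0.02)
    return (
        MetaboliteSpec("purine_pass", 6, 5, {
            GROUP_CONTROL: 0.20, GROUP_SEN: 0.50, GROUP_SHHK2: 0.25,
            GROUP_WT: 0.45, GROUP_MUT: 0.25}, True),
        MetaboliteSpec("null_met", 6, 5, {g: 0.30 for g in ALL_GROUPS}, False),
        MetaboliteSpec("mut_rescued", 6, 5, {
            GROUP_CONTROL: 0.20, GROUP_SEN: 0.50, GROUP_SHHK2: 0.25,
            GROUP_WT: 0.45, GROUP_MUT: 0.44}, False),
    )


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study, with 1/10-scale defaults."""

    seed: int = 0
    chrom_sizes: tuple[int, ...] = (15_000_000, 15_000_000,
                                    15_000_000, 15_000_000)
    n_genes: int = 500
    gene_len_range: tuple[int, int] = (2_000, 8_000)
    gene_gap_range: tuple[int, int] = (5_000, 20_000)

    # loops
    delta_ep_values: tuple[int, ...] = (-3, -2, -1, 0, 1, 2, 3)
    extra_ep_range: tuple[int, int] = (0, 2)   # baseline EP# on top of |delta|
    n_background_loops: int = 1_000            # per condition
    background_trans_fraction: float = 0.1
    ep_distance_range: tuple[int, int] = (10_000, 1_500_000)
    anchor_width: int = 400

    # expression coupling
    coupling_slope: float = 0.05
    coupling_noise_sd: float = 0.1
    n_mtc_genes: int = 10
    mtc_up_lfc: float = 2.0
    kd_down_lfc: float = 2.0
    planted_padj: float = 1e-4

    # m6A
    n_poly_transcripts: int = 52
    n_poly_down: int = 4
    poly_site_range: tuple[int, int] = (4, 8)
    nonpoly_site_range: tuple[int, int] = (1, 3)
    n_nonpoly_with_sites: int = 150
    peak_width: int = 100
    m6a_down_lfc: float = 2.0

    # isotope tracing
    panel: tuple[MetaboliteSpec, ...] = field(default_factory=_default_panel)
    n_replicates: int = 3
    intensity_scale: float = 1e6
    intensity_noise_sigma: float = 0.02   # lognormal sigma; 0 = noise-free
    p13c: float = DEFAULT_P13C

    # qPCR
    ct_noise_sd: float = 0.2

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per generator."""
        return np.random.default_rng([self.seed, stream])


# --------------------------------------------------------------------------
# genome

def generate_genome(cfg: GeneratorConfig) -> tuple[GeneCatalog, dict[str, int]]:
    """Non-overlapping gene models with strands, TSS and UTR/CDS/UTR segments.

    Genes are laid left to right per chromosome with random gaps; each gene
    is split contiguously into 5'UTR (10%), CDS (70%) and 3'UTR (20%)
    oriented by strand.
    """
    rng = cfg.rng(1)
    sizes = {f"chr{i + 1}": s for i, s in enumerate(cfg.chrom_sizes)}
    chroms = list(sizes)
    genes = []
    per_chrom = {c: 0 for c in chroms}
    for i in range(cfg.n_genes):
        per_chrom[chroms[i % len(chroms)]] += 1
    gi = 0
    for chrom in chroms:
        pos = int(rng.integers(*cfg.gene_gap_range))
        for _ in range(per_chrom[chrom]):
            length = int(rng.integers(*cfg.gene_len_range))
            if pos + length >= sizes[chrom]:
                raise ValueError(
                    f"genes do not fit on {chrom}; use larger chromosomes")
            strand = "+" if rng.random() < 0.5 else "-"
            start, end = pos, pos + length
            l5 = max(1, int(0.1 * length))
            l3 = max(1, int(0.2 * length))
            if strand == "+":
                segs = {"5UTR": (start, start + l5),
                        "CDS": (start + l5, end - l3),
                        "3UTR": (end - l3, end)}
            else:
                segs = {"3UTR": (start, start + l3),
                        "CDS": (start + l3, end - l5),
                        "5UTR": (end - l5, end)}
            regions = {lab: (GenomicInterval(chrom, lo, hi),)
                       for lab, (lo, hi) in segs.items()}
            genes.append(GeneModel(f"G{gi:04d}", chrom, strand, start, end,
                                   regions))
            gi += 1
            pos = end + int(rng.integers(*cfg.gene_gap_range))
    return GeneCatalog(genes), sizes


# --------------------------------------------------------------------------
# loops

def _interval_clear_of(trees, chrom, start, end) -> bool:
    tree = trees.get(chrom)
    return tree is None or not tree.overlap(start, end)


def generate_loops(cfg: GeneratorConfig, catalog: GeneCatalog,
                   chrom_sizes: Mapping[str, int],
                   ) -> tuple[dict[str, list[Loop]], pd.DataFrame]:
    """Two-condition loop sets with planted per-gene EP counts.

    For every gene a delta EP# is drawn from ``delta_ep_values``; the gene
    receives ``max(0, -delta) + extra`` EP loops in the growing condition
    and that plus delta in the senescent condition.  Each planted loop has
    one anchor inside the promoter window and one at a distal site placed
    5 kb - 2 Mb away and rejected if it would touch any promoter.  FDR and
    read counts are drawn so the H3K27Ac significance filter keeps exactly
    the planted loops; background loops avoid promoters entirely.

    Returns the loops per condition and the per-gene truth table
    (ep_growing, ep_senescent, delta_ep).
    """
    rng = cfg.rng(2)
    promoters = define_promoters(catalog)
    from intervaltree import IntervalTree
    trees: dict[str, IntervalTree] = {}
    for pw in promoters:
        trees.setdefault(pw.interval.chrom, IntervalTree()).addi(
            pw.interval.start, pw.interval.end, pw.gene_id)

    half = cfg.anchor_width // 2
    truth_rows = []
    loops: dict[str, list[Loop]] = {"growing": [], "senescent": []}
    for g in catalog:
        delta = int(rng.choice(cfg.delta_ep_values))
        base = max(0, -delta) + int(rng.integers(cfg.extra_ep_range[0],
                                                 cfg.extra_ep_range[1] + 1))
        n_grow, n_sen = base, base + delta
        truth_rows.append({"gene_id": g.gene_id, "ep_growing": n_grow,
                           "ep_senescent": n_sen, "delta_ep": delta})
        for cond, n in (("growing", n_grow), ("senescent", n_sen)):
            for _ in range(n):
                a = GenomicInterval(g.chrom, max(0, g.tss - half),
                                    g.tss + half)
                for _ in range(100):
                    d = int(rng.integers(*cfg.ep_distance_range))
                    pos = g.tss + d if rng.random() < 0.5 else g.tss - d
                    if not half <= pos <= chrom_sizes[g.chrom] - half:
                        pos = g.tss + d
                        if pos > chrom_sizes[g.chrom] - half:
                            pos = g.tss - d
                    if pos < half:
                        continue
                    if _interval_clear_of(trees, g.chrom, pos - half,
                                          pos + half):
                        break
                else:  # pragma: no cover - pathological config
                    raise RuntimeError("could not place distal anchor")
                b = GenomicInterval(g.chrom, pos - half, pos + half)
                loops[cond].append(Loop(
                    a, b, int(rng.integers(4, 31)),
                    float(rng.uniform(0, 0.009)), assay="H3K27Ac",
                    condition=cond))

    chroms = list(chrom_sizes)
    for cond in loops:
        for _ in range(cfg.n_background_loops):
            trans = rng.random() < cfg.background_trans_fraction
            c1 = chroms[int(rng.integers(len(chroms)))]
            c2 = chroms[int(rng.integers(len(chroms)))] if trans else c1
            anchors = []
            for c in (c1, c2):
                for _ in range(100):
                    pos = int(rng.integers(half, chrom_sizes[c] - half))
                    if _interval_clear_of(trees, c, pos - half, pos + half):
                        anchors.append(GenomicInterval(c, pos - half,
                                                       pos + half))
                        break
                else:  # pragma: no cover
                    raise RuntimeError("could not place background anchor")
            significant = rng.random() < 0.5
            reads = int(rng.integers(4, 31)) if significant \
                else int(rng.integers(0, 4))
            fdr = float(rng.uniform(0, 0.009)) if significant \
                else float(rng.uniform(0.02, 1.0))
            loops[cond].append(Loop(anchors[0], anchors[1], reads, fdr,
                                    assay="H3K27Ac", condition=cond))
    return loops, pd.DataFrame(truth_rows)


# --------------------------------------------------------------------------
# expression

def generate_expression(cfg: GeneratorConfig, truth_ep: pd.DataFrame,
                        ) -> tuple[pd.DataFrame, frozenset[str]]:
    """Expression tables for the three contrasts, coupled to delta EP#.

    sen_vs_growing log FC = slope * delta_ep + N(0, sd), plus an additive
    up-shift for a planted MTC-dependent subset drawn from genes with
    delta_ep > 0; the knockdown contrasts reverse exactly that subset.
    Planted genes get ``planted_padj``; all others draw padj uniformly.

    Returns the long-form table and the planted MTC-dependent gene set.
    """
    rng = cfg.rng(3)
    genes = truth_ep["gene_id"].to_numpy()
    delta = truth_ep["delta_ep"].to_numpy(float)
    enhanced = genes[delta > 0]
    if len(enhanced) < cfg.n_mtc_genes:
        raise ValueError("not enough contact-enhanced genes to plant the "
                         "MTC-dependent subset")
    mtc = frozenset(map(str, rng.choice(enhanced, size=cfg.n_mtc_genes,
                                        replace=False)))
    is_mtc = np.array([g in mtc for g in genes])

    score = np.exp(rng.normal(3.0, 1.0, size=len(genes)))
    noise = (rng.normal(0.0, cfg.coupling_noise_sd, size=(3, len(genes)))
             if cfg.coupling_noise_sd > 0 else np.zeros((3, len(genes))))

    frames = []
    lfc_sen = cfg.coupling_slope * delta + noise[0] \
        + np.where(is_mtc, cfg.mtc_up_lfc, 0.0)
    padj_sen = np.where(is_mtc, cfg.planted_padj, rng.uniform(0, 1, len(genes)))
    frames.append(pd.DataFrame({
        "gene_id": genes, "contrast": "sen_vs_growing", "score": score,
        "log_fc": lfc_sen, "padj": padj_sen}))
    for i, contrast in enumerate(("shMETTL3_vs_sen", "shMETTL14_vs_sen"),
                                 start=1):
        lfc = noise[i] + np.where(is_mtc, -cfg.kd_down_lfc, 0.0)
        padj = np.where(is_mtc, cfg.planted_padj,
                        rng.uniform(0, 1, len(genes)))
        frames.append(pd.DataFrame({
            "gene_id": genes, "contrast": contrast, "score": score,
            "log_fc": lfc, "padj": padj}))
    return pd.concat(frames, ignore_index=True), mtc


# --------------------------------------------------------------------------
# m6A

def generate_m6a(cfg: GeneratorConfig, catalog: GeneCatalog,
                 ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """m6A peak calls with planted site counts plus a matching RNA-seq table.

    A planted subset of transcripts gets more than three disjoint peaks
    (polymethylated); of those, ``n_poly_down`` are also planted as
    downregulated in the expression table.  Peaks are spaced so that
    merging never changes the planted count.

    Returns (peaks, expression, truth) where truth holds the planted site
    counts and the polymethylated / downregulated sets.
    """
    rng = cfg.rng(4)
    gene_ids = np.array(catalog.gene_ids)
    n_with = cfg.n_poly_transcripts + cfg.n_nonpoly_with_sites
    if n_with > len(gene_ids):
        raise ValueError("not enough genes for the requested m6A layout")
    chosen = [str(g) for g in rng.choice(gene_ids, size=n_with,
                                         replace=False)]
    poly = frozenset(chosen[:cfg.n_poly_transcripts])
    down = frozenset(map(str, rng.choice(sorted(poly), size=cfg.n_poly_down,
                                         replace=False)))

    counts: dict[str, int] = {}
    rows = []
    for tid in chosen:
        g = catalog[tid]
        lo, hi = cfg.poly_site_range if tid in poly else cfg.nonpoly_site_range
        k = int(rng.integers(lo, hi + 1))
        counts[tid] = k
        span = g.end - g.start - cfg.peak_width - 20
        stride = span // k
        for j in range(k):
            jitter = int(rng.integers(0, max(1, stride - cfg.peak_width)))
            s = g.start + 10 + j * stride + jitter
            rows.append({"transcript_id": tid, "chrom": g.chrom,
                         "start": s, "end": s + cfg.peak_width,
                         "signal": float(np.exp(rng.normal(1.0, 0.5)))})
    peaks = pd.DataFrame(rows)

    lfc = rng.normal(0.0, 0.2, size=len(gene_ids))
    padj = rng.uniform(0, 1, size=len(gene_ids))
    is_down = np.array([g in down for g in gene_ids])
    lfc = np.where(is_down, -cfg.m6a_down_lfc, lfc)
    padj = np.where(is_down, cfg.planted_padj, padj)
    expression = pd.DataFrame({
        "gene_id": gene_ids, "contrast": "sen_vs_growing",
        "score": np.exp(rng.normal(3.0, 1.0, size=len(gene_ids))),
        "log_fc": lfc, "padj": padj})
    truth = {"site_counts": counts, "polymethylated": sorted(poly),
             "poly_down": sorted(down)}
    return peaks, expression, truth


# --------------------------------------------------------------------------
# isotope tracing

def generate_isotopologues(cfg: GeneratorConfig,
                           ) -> tuple[pd.DataFrame, dict]:
    """Raw isotopologue intensity table for the five-group tracing design.

    For each metabolite/group/replicate the planted MID (all mass in M+0
    and the labeled M+m species) is forward-convolved with the binomial
    natural-abundance kernel, scaled, and multiplied by lognormal noise.

    Returns (table, truth) with truth holding expected screen outcomes and
    the screened isotopologue index per metabolite.
    """
    rng = cfg.rng(5)
    max_n = max(spec.n_carbons for spec in cfg.panel)
    rows = []
    for spec in cfg.panel:
        A = natural_abundance_matrix(spec.n_carbons, cfg.p13c)
        for group in ALL_GROUPS:
            f = spec.fractions[group]
            mid = np.zeros(spec.n_carbons + 1)
            mid[0], mid[spec.m_label] = 1.0 - f, f
            expected = A @ mid * cfg.intensity_scale
            for rep in range(1, cfg.n_replicates + 1):
                if cfg.intensity_noise_sigma > 0:
                    raw = expected * np.exp(rng.normal(
                        0.0, cfg.intensity_noise_sigma, size=expected.size))
                else:
                    raw = expected.copy()
                row = {"metabolite": spec.name, "n_carbons": spec.n_carbons,
                       "group": group, "replicate": rep}
                for i in range(max_n + 1):
                    row[f"M+{i}"] = float(raw[i]) if i < raw.size else 0.0
                rows.append(row)
    truth = {"expected_pass": {s.name: s.expected_pass for s in cfg.panel},
             "m_label": {s.name: s.m_label for s in cfg.panel}}
    return pd.DataFrame(rows), truth


# --------------------------------------------------------------------------
# qPCR

def generate_ct_table(cfg: GeneratorConfig, true_fold: float = 4.0,
                      n_replicates: int | None = None) -> tuple[pd.DataFrame, dict]:
    """A two-sample Ct table whose planted 2^-ddCt fold change is known."""
    rng = cfg.rng(6)
    n = n_replicates or cfg.n_replicates
    rows = []
    base_target, base_ref = 24.0, 18.0
    for rep in range(1, n + 1):
        for sample, shift in (("calibrator", 0.0),
                              ("treated", -np.log2(true_fold))):
            rows.append({
                "sample": sample, "replicate": rep, "target": "HK2",
                "target_ct": base_target + shift
                + float(rng.normal(0, cfg.ct_noise_sd)),
                "reference_ct": base_ref
                + float(rng.normal(0, cfg.ct_noise_sd))})
    return pd.DataFrame(rows), {"true_fold": true_fold}


# --------------------------------------------------------------------------
# bundle

def generate_all(cfg: GeneratorConfig, outdir: str | os.PathLike) -> dict:
    """Write every synthetic input plus a ground-truth manifest to a directory.

    Emits genes.gtf, loops_<condition>.bedpe, expression.csv,
    m6a_peaks.csv, m6a_expression.csv, isotopologues.csv, ct.csv and
    truth.json; returns the truth manifest.
    """
    os.makedirs(outdir, exist_ok=True)
    catalog, sizes = generate_genome(cfg)
    write_gene_models_gtf(catalog, os.path.join(outdir, "genes.gtf"))
    loops, truth_ep = generate_loops(cfg, catalog, sizes)
    for cond, lps in loops.items():
        write_loops(lps, os.path.join(outdir, f"loops_{cond}.bedpe"))
    expression, mtc = generate_expression(cfg, truth_ep)
    write_table(expression, os.path.join(outdir, "expression.csv"))
    peaks, m6a_expr, m6a_truth = generate_m6a(cfg, catalog)
    write_table(peaks, os.path.join(outdir, "m6a_peaks.csv"))
    write_table(m6a_expr, os.path.join(outdir, "m6a_expression.csv"))
    iso, iso_truth = generate_isotopologues(cfg)
    write_table(iso, os.path.join(outdir, "isotopologues.csv"))
    ct, ct_truth = generate_ct_table(cfg)
    write_table(ct, os.path.join(outdir, "ct.csv"))

    truth = {
        "chrom_sizes": sizes,
        "ep_counts": truth_ep.to_dict(orient="list"),
        "mtc_genes": sorted(mtc),
        "m6a": m6a_truth,
        "isotopologues": iso_truth,
        "qpcr": ct_truth,
    }
    with open(os.path.join(outdir, "truth.json"), "w", newline="\n") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth
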