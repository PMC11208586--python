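# loopmet

Integrative analysis of enhancer–promoter chromatin loops, nascent
transcription, m⁶A polymethylation, and ¹³C-glucose tracing in cellular
senescence studies.

Oncogene-induced senescent fibroblasts rewire their 3D genome: the
METTL3/METTL14 methyltransferase complex (MTC) drives changes in
enhancer–promoter (EP) contacts that activate metabolic genes such as
hexokinase 2 (HK2), reprogramming glucose metabolism and ultimately the
fate of polymethylated m⁶A mRNAs. Testing that chain of reasoning requires
several unglamorous but exacting computations — loop significance
filtering, per-gene EP counting, outlier-robust correlation of contact
changes with transcription, multi-site m⁶A classification,
natural-abundance correction of mass-isotopomer distributions, and
comparative-Ct quantitation. `loopmet` packages those computations as a
tested, importable library for genomicists who have loop calls, peak
calls, and isotopologue tables in hand and want the integration done
reproducibly.

Everything is exercised end-to-end on synthetic data with planted ground
truth (`loopmet.synthetic`), so every stage is testable without any
sequencing download.

## The computations

**EP loops.** A HiChIP loop (anchors *a*, *b*; read count *n*; FDR *q*)
is significant when *q* < 0.01 and *n* ≥ 4 (H3K27Ac) or *q* < 0.05
(METTL3). Promoters are TSS ± 1 kb; a significant loop is an EP
interaction if either anchor overlaps a promoter by ≥ 1 bp. EP#(*g*, *c*)
counts a gene's EP loops in condition *c*, and ΔEP# = EP#(senescent) −
EP#(growing) by default (sign configurable). Intra-chromosomal loops are
classed by anchor-midpoint separation *d*: short (*d* < 5 kb), medium
(5 kb ≤ *d* ≤ 2 Mb), long (*d* > 2 Mb).

**Coupling to transcription.** Genes are grouped by ΔEP#; from each group
70 genes are resampled 200 times and each draw's mean log₂FC recorded;
Pearson *r* (two-sided *p* via the *t* transform, *n* − 2 df) is computed
between group ΔEP# and the grand means. A candidate funnel then keeps
genes up in senescence (log₂FC ≥ 1, padj < 0.05), down on knockdown of
both METTL3 and METTL14, and with ΔEP# > 0.

**m⁶A polymethylation.** Peaks are merged into unique sites per
transcript (overlaps collapse, signal = max; region assigned by midpoint
among 5′UTR/CDS/3′UTR); a transcript with **more than three** sites is
polymethylated; the polymethylated ∩ downregulated set is reported.

**¹³C tracing.** Measured isotopologue vectors are modeled as the true
mass-isotopomer distribution (MID) convolved with the binomial natural
¹³C kernel (p = 0.0107); the MID is recovered by non-negative least
squares and normalized to Σ = 1. Labeled fractions (e.g. M+5) feed a
three-criterion screen over the five-arm design (control; senescent
shControl; senescent shHK2; shHK2 + WT HK2; shHK2 + mutant HK2):
labeling up in senescence, down on HK2 knockdown, rescued by wildtype but
not mutant HK2 (two-tailed Student's *t*, α = 0.05).

**qPCR.** 2^−ΔΔCt fold changes (multi-reference Cts combined by geometric
mean), 3C comparative-Ct ligation frequencies with a non-peak-control
pair, and translational efficiency (polysome/free signal).

Contact matrices can also be ICE-balanced (30 iterations, zero bins
preserved, mass conserved) and display-capped at the top-5% score.

## Worked example

`python examples/resampling_correlation.py` — plants log₂FC =
0.05·ΔEP# + N(0, 0.1) over 500 genes and recovers the coupling:

```
 delta_ep  n_genes  with_replacement  grand_mean_log_fc
       -3       88             False            -0.1527
       -2       56              True            -0.0896
       -1       68              True            -0.0427
        0       73             False             0.0002
        1       65              True             0.0593
        2       82             False             0.1081
        3       68              True             0.1660

Pearson r = 0.9991, two-sided p = 4.78e-08
```

Each row is one ΔEP# group; the grand mean is the average over 200 draws
of 70 genes, and the near-perfect *r* shows the planted slope (≈ 0.05
log₂FC per loop gained) surviving the resampling. Similarly,
`examples/m6a_polymethylation.py` recovers the planted one-tenth-scale
funnel — 52 polymethylated transcripts of which 4 are downregulated —
exactly, and `examples/isotope_screen.py` passes only the metabolite
planted with the full rescue pattern. `examples/full_pipeline.py` (or
`loopmet run --config cfg.yaml --outdir out`) runs every stage from one
seeded config and writes deterministic CSVs plus a checksummed manifest.

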