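# Methods

This note records the models implemented in `loopmet`, the conventions and
defaults that matter, what the synthetic generator does and does not
emulate, and the design choices made where the analysis was genuinely
open.

## Coordinates and formats

All coordinates are 0-based half-open internally. BED/BEDPE files are read
as-is; GTF (1-based inclusive) is converted on input. The TSS of a
+ strand gene is its start; of a − strand gene, `end − 1` (the last base
under the half-open convention). Loop files are BEDPE-like with a
configurable column layout (`LoopDialect`), because loop-caller outputs
differ in where the read count and FDR live; the default is
`chrA startA endA chrB startB endB name count fdr`. Intra-chromosomal
anchors are canonicalized left-to-right on construction. All writers emit
a fixed column order and LF endings, and tables are read back with
round-trip float parsing, so read→write→read is an identity — the
property the pipeline's checksum cache and byte-determinism guarantees
rest on.

## Loop analytics

Significance is per assay: H3K27Ac HiChIP keeps loops with FDR < 0.01 and
≥ 4 reads; METTL3 HiChIP keeps FDR < 0.05 with no read floor (the read
floor is attached only to the stricter FDR rule; both thresholds are
overridable). The FDR column is treated as an opaque probability — no
assumption about how the caller computed it.

Loop distance is the absolute difference of anchor midpoints. Midpoint
(rather than gap) distance is used because anchor widths vary with
restriction-fragment padding; with the strict/closed boundary choices —
short *d* < 5 kb, medium 5 kb ≤ *d* ≤ 2 Mb, long *d* > 2 Mb — the three
classes partition every intra-chromosomal loop. Inter-chromosomal loops
are reported as `trans` and excluded from the three classes.

Promoter windows are TSS ± 1 kb (strand-independent, clipped at 0). EP
assignment uses half-open overlap of ≥ 1 bp on *either* anchor; a
promoter–promoter loop counts for both genes, and a loop counts once per
(loop, gene) even when both anchors hit the same promoter. ΔEP# defaults
to senescent − growing, so contact gain is positive; the opposite
orientation is one flag away and both are tested.

ICE balancing runs a fixed 30 rounds (an optional tolerance allows early
stopping in tests): each round divides the matrix by the outer product of
row-sum biases renormalized to mean 1; structurally empty bins are
excluded and stay exactly zero; total mass is rescaled to the input mass
at the end. Symmetry is preserved by construction. Display capping
replaces values above the (1 − q) quantile of nonzero entries (default
q = 0.05) with that quantile; the quantile is taken as an order statistic
(`method="lower"`), which makes capping idempotent.

## Transcription coupling and the candidate funnel

The grouped resampling draws `group_size = 70` genes `reps = 200` times
per ΔEP# group — without replacement when the group is large enough, with
replacement otherwise, so sparse tail groups are kept and flagged by a
per-group `with_replacement` column rather than silently dropped. Pearson
*r* and its two-sided *p* (via the *t* transform with *n* − 2 df) are
computed on group grand means. A separate `correlate_candidates` computes
the same statistic on raw per-gene (ΔEP#, log₂FC) pairs for small
candidate lists; the two are distinct operations because both analyses
are standard and answer different questions (population trend vs
candidate-level association).

The funnel thresholds default to |log₂FC| ≥ 1 and padj < 0.05 — a
conventional differential-expression cut, fully configurable and recorded
in the run manifest. The knockdown requirement defaults to *both* METTL3
and METTL14 (the Venn-overlap reading); an either-KD mode is available.
Contact enhancement is strict (ΔEP# > 0), so unchanged genes never enter
the final set. Tightening any threshold can only shrink the sets
(monotonicity is property-tested).

## m⁶A polymethylation

"Unique sites" are peaks merged per transcript: overlapping peaks (on the
half-open convention, touching peaks do not overlap) collapse into one
site carrying the maximum signal, which avoids double-counting
summit-split peaks. Each site's region (5′UTR/CDS/3′UTR) is the segment
containing its midpoint — the simplest unambiguous rule. Polymethylation
is strict: site count > 3. The representative signal per transcript is
the maximum over its sites. Peaks are supplied in genomic coordinates
with a transcript id; counting is invariant to input order.

## Isotope tracing

The correction matrix for an *n*-carbon metabolite is lower-triangular:
column *k* holds the binomial mass distribution of the *n* − *k*
unlabeled carbons at natural abundance p = 0.0107, shifted by *k*; every
column sums to 1. Only carbon is corrected — matching the
carbon-isotopologue framing of the measurements — which is a documented
simplification relative to full elemental (N/H/O) correction. The MID is
recovered by non-negative least squares rather than inversion so noisy
data cannot produce negative fractions; on noise-free input the two
coincide (round-trip error ~1e-16, property-tested to 1e-9 for all
n ≤ 12). Corrected MIDs are normalized to sum to 1.

The screen compares group means of a chosen labeled fraction (default the
M+5 species, the purine signature of labeled ribose) with two-tailed
equal-variance *t* tests at α = 0.05 (Welch available by flag). Criterion
c encodes "rescued by wildtype but not mutant" as: WT significantly above
knockdown, and mutant *not* significantly above knockdown; an optional
effect-size gate additionally requires the mutant mean below the
knockdown/WT midpoint (off by default). Metabolites missing a group are
flagged untestable and never pass.

## qPCR utilities

ΔCt subtracts the geometric mean of the reference-gene Cts (a single
reference degenerates correctly); fold change is 2^−ΔΔCt against a
calibrator. Self-calibration gives exactly 1 and global Ct shifts cancel
— both identities are tested. 3C ligation frequency applies the same
comparative-Ct transform per primer pair against the calibrator sample,
reporting the non-peak-control pair as the background reference (a
missing NPC warns but does not fail). Translational efficiency is the
polysome-fraction signal over the free-mRNA signal.

## Synthetic data

The generator runs at one tenth of a typical study's cardinalities — 500
genes on four 15-Mb chromosomes, ~2,000 loops per condition, 52
polymethylated transcripts of which 4 downregulated (mirroring the
523 → 35 funnel shape), a 3-metabolite five-group tracing panel with
n = 3 replicates — so the full suite runs in seconds. Key defaults:
coupling log₂FC = 0.05·ΔEP# + N(0, 0.1) with ΔEP# ∈ {−3…+3}; a 10-gene
MTC-dependent contact-enhanced subset planted with a +2 log₂FC up-shift
in senescence reversed in both knockdown contrasts; lognormal
multiplicative intensity noise (σ = 0.02, about one tenth of the planted
labeled-fraction effects); Gaussian Ct noise (SD 0.2 cycles). Planted EP
loops place one anchor inside the promoter and the distal anchor 10 kb –
1.5 Mb away, rejected if it would touch any other promoter, and draw
FDR/read counts that pass the significance filter; background loops avoid
promoters entirely. This makes planted truth recover *exactly* through
the EP stage, which is what the oracle-equivalence tests exploit.

Every generator is a pure function of its config (child RNG streams are
derived from the seed per generator), so identical configs produce
byte-identical files.

What the generator does not emulate: read-level data and mapping
artifacts, overdispersed count noise, correlated replicates, peaks
spanning region boundaries, incomplete annotation, and metabolite
interconversion. Passing tests therefore demonstrate the correctness of
the computations under the stated models, not robustness to every
pathology of real sequencing or LC-MS data.

## Pipeline

One YAML config drives all stages (io → loops → integration; io → m⁶A;
io → tracing); every result-affecting threshold is snapshotted into
`manifest.json` together with input checksums and per-stage row counts.
Reruns skip a stage when the SHA-256 of (config + input hashes) matches
and its outputs exist. Reports and manifests exclude volatile fields
(timings, skip flags), so two runs from one config are byte-identical.

## Known limitations

- EP counting treats a loop touching two promoters as one EP event for
  each gene; no sensitivity analysis of the alternative once-per-anchor
  convention is built in.
- Carbon-only natural-abundance correction slightly overestimates labeled
  fractions for metabolites with many exchangeable heteroatoms.
- The screen's criterion c is a significance pattern, not an equivalence
  test; a mutant rescue just below significance counts as "no rescue".
- ICE is plain row-sum balancing; no MAD-max filtering of sparse bins.
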