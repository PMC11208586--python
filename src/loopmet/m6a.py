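"""m6A polymethylation calling.

A transcript's "sites" are its m6A peaks after merging overlapping peaks
(keeping the larger signal), each assigned to the 5'UTR/CDS/3'UTR segment
containing its midpoint.  A transcript with more than three sites (strict)
is polymethylated; polymethylated transcripts that are also downregulated
form the candidate set for stress-granule sequestration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .genomic_io import GeneCatalog, GenomicInterval, REGION_LABELS

logger = logging.getLogger(__name__)

#: "more than three sites" -- strict exclusive threshold
DEFAULT_MIN_SITES_EXCLUSIVE = 3


@dataclass(frozen=True)
class M6ASite:
    """One merged m6A site on a transcript."""

    transcript_id: str
    region: str
    interval: GenomicInterval
    signal: float

    def __post_init__(self):
        if self.region not in REGION_LABELS:
            raise ValueError(f"invalid region {self.region!r}")
        if self.signal < 0:
            raise ValueError("negative signal")


def _assign_region(catalog: GeneCatalog, transcript_id: str,
                   midpoint: float) -> str | None:
    gene = catalog[transcript_id]
    for label in REGION_LABELS:
        for iv in gene.regions.get(label, ()):
            if iv.start <= midpoint < iv.end:
                return label
    return None


def count_unique_sites(peaks: pd.DataFrame,
                       catalog: GeneCatalog) -> dict[str, list[M6ASite]]:
    """Merge peaks into unique sites per transcript.

    ``peaks`` columns: transcript_id, chrom, start, end, signal (genomic
    coordinates).  Peaks on transcripts absent from the catalog are logged
    and skipped; peaks whose midpoint falls outside any annotated region
    (e.g. intronic) are likewise skipped.  Overlapping peaks within a
    transcript are merged into one site whose signal is the maximum.
    The result is independent of peak input order.
    """
    sites: dict[str, list[M6ASite]] = {}
    for tid, sub in peaks.groupby("transcript_id", sort=True):
        if tid not in catalog:
            logger.warning("transcript %s absent from catalog; %d peaks skipped",
                           tid, len(sub))
            continue
        merged: list[list] = []  # [start, end, signal]
        for _, row in sub.sort_values(["start", "end"]).iterrows():
            s, e, sig = int(row["start"]), int(row["end"]), float(row["signal"])
            if merged and s < merged[-1][1]:  # half-open overlap with previous
                merged[-1][1] = max(merged[-1][1], e)
                merged[-1][2] = max(merged[-1][2], sig)
            else:
                merged.append([s, e, sig])
        chrom = catalog[tid].chrom
        out = []
        for s, e, sig in merged:
            region = _assign_region(catalog, tid, (s + e) / 2.0)
            if region is None:
                logger.debug("peak midpoint outside annotated regions of %s", tid)
                continue
            out.append(M6ASite(tid, region, GenomicInterval(chrom, s, e), sig))
        if out:
            sites[tid] = out
    return sites


def classify_polymethylated(site_sets: dict[str, list[M6ASite]],
                            min_sites_exclusive: int = DEFAULT_MIN_SITES_EXCLUSIVE,
                            ) -> pd.DataFrame:
    """Per-transcript polymethylation call.

    A transcript is polymethylated iff its merged site count strictly
    exceeds ``min_sites_exclusive`` (default: more than three).  The
    representative signal is the maximum over the transcript's sites
    (NaN when it has none).
    """
    rows = []
    for tid in sorted(site_sets):
        sites = site_sets[tid]
        n = len(sites)
        rows.append({
            "transcript_id": tid,
            "site_count": n,
            "is_polymethylated": n > min_sites_exclusive,
            "representative_signal": max((s.signal for s in sites),
                                         default=float("nan")),
        })
    return pd.DataFrame(rows, columns=["transcript_id", "site_count",
                                       "is_polymethylated",
                                       "representative_signal"])


def intersect_downregulated(calls: pd.DataFrame, expression: pd.DataFrame,
                            down_lfc: float = 1.0, alpha: float = 0.05,
                            contrast: str = "sen_vs_growing") -> frozenset[str]:
    """Polymethylated transcripts that are also downregulated.

    Keeps polymethylated transcripts with log_fc <= -down_lfc and
    padj < alpha in the given contrast; transcripts without an expression
    record are excluded with a warning.
    """
    sub = expression[expression["contrast"] == contrast].set_index("gene_id")
    poly = calls.loc[calls["is_polymethylated"], "transcript_id"]
    kept = []
    for tid in poly:
        if tid not in sub.index:
            logger.warning("no expression record for %s; excluded", tid)
            continue
        rec = sub.loc[tid]
        if rec["log_fc"] <= -down_lfc and rec["padj"] < alpha:
            kept.append(str(tid))
    return frozenset(kept)
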