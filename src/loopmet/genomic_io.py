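"""Readers and writers for the text formats the pipeline touches.

All coordinates are 0-based, half-open internally.  BED/BEDPE files are
read as-is; GTF coordinates (1-based, inclusive) are converted on input.
Every record is validated on construction, and malformed lines fail hard
with the offending line number.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

logger = logging.getLogger(__name__)

#: transcript-region labels used throughout (ASCII stand-ins for 5'UTR etc.)
REGION_LABELS = ("5UTR", "CDS", "3UTR")

#: assays with distinct loop-significance rules
KNOWN_ASSAYS = ("H3K27Ac", "METTL3")


class FormatError(ValueError):
    """A malformed record in an input file; carries the 1-based line number."""

    def __init__(self, message: str, path: str | os.PathLike | None = None,
                 line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = str(path) if path is not None else None
        self.line = line


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval [{self.start}, {self.end})")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open overlap by at least one base."""
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


@dataclass(frozen=True)
class Loop:
    """A chromatin loop: two anchors with read support and an FDR.

    Intra-chromosomal anchors are stored left-to-right
    (``anchor_a.start <= anchor_b.start``); inter-chromosomal pairs are
    kept in input order.
    """

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    read_count: int
    fdr: float
    assay: str = "H3K27Ac"
    condition: str = ""

    def __post_init__(self):
        if self.read_count < 0:
            raise ValueError(f"negative read_count {self.read_count}")
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"FDR {self.fdr} outside [0, 1]")
        if (self.is_intra and self.anchor_a.start > self.anchor_b.start):
            a, b = self.anchor_a, self.anchor_b
            object.__setattr__(self, "anchor_a", b)
            object.__setattr__(self, "anchor_b", a)

    @property
    def is_intra(self) -> bool:
        return self.anchor_a.chrom == self.anchor_b.chrom

    @property
    def span(self) -> float:
        """Anchor midpoint separation; only defined for intra-chromosomal loops."""
        if not self.is_intra:
            raise ValueError("span undefined for inter-chromosomal loops")
        return abs(self.anchor_b.midpoint - self.anchor_a.midpoint)


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS and labeled transcript-region segments."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    regions: Mapping[str, tuple[GenomicInterval, ...]] = field(default_factory=dict)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if not (self.start <= self.tss < self.end):
            raise ValueError(f"TSS outside gene span for {self.gene_id}")
        for label, ivs in self.regions.items():
            if label not in REGION_LABELS:
                raise ValueError(f"unknown region label {label!r} for {self.gene_id}")
            for iv in ivs:
                if iv.start < self.start or iv.end > self.end:
                    raise ValueError(
                        f"{label} segment {iv} outside span of {self.gene_id}")

    @property
    def tss(self) -> int:
        # half-open convention: last base of a minus-strand gene is end - 1
        return self.start if self.strand == "+" else self.end - 1


class GeneCatalog:
    """An ordered collection of gene models with id lookup."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._genes = list(genes)
        self._by_id = {}
        for g in self._genes:
            if g.gene_id in self._by_id:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            self._by_id[g.gene_id] = g

    def __iter__(self):
        return iter(self._genes)

    def __len__(self):
        return len(self._genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self._genes]


@dataclass(frozen=True)
class LoopDialect:
    """Column layout of a BEDPE-like loop file.

    hichipper-style outputs vary in where the read count and FDR live;
    the defaults match ``chrA startA endA chrB startB endB name count fdr``.
    """

    count_col: int = 7
    fdr_col: int = 8
    n_min_cols: int = 8


DEFAULT_DIALECT = LoopDialect()


def read_loops(path: str | os.PathLike, dialect: LoopDialect = DEFAULT_DIALECT,
               assay: str = "H3K27Ac", condition: str = "") -> list[Loop]:
    """Read a BEDPE-like loop file, validating every record.

    Lines starting with ``#`` are skipped.  An empty file yields an empty
    list with a warning.  Any malformed field raises :class:`FormatError`
    naming the line.
    """
    loops: list[Loop] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < max(dialect.n_min_cols,
                                 dialect.count_col + 1, dialect.fdr_col + 1):
                raise FormatError(
                    f"expected >= {dialect.n_min_cols} tab-separated columns, "
                    f"got {len(fields)}", path, lineno)
            try:
                a = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                b = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
                loop = Loop(a, b, int(fields[dialect.count_col]),
                            float(fields[dialect.fdr_col]),
                            assay=assay, condition=condition)
            except (ValueError, IndexError) as exc:
                raise FormatError(str(exc), path, lineno) from exc
            loops.append(loop)
    if not loops:
        logger.warning("no loops read from %s", path)
    return loops


def write_loops(loops: Sequence[Loop], path: str | os.PathLike) -> None:
    """Write loops as 9-column BEDPE (deterministic order and line endings)."""
    with open(path, "w", newline="\n") as fh:
        for lp in loops:
            fh.write("\t".join([
                lp.anchor_a.chrom, str(lp.anchor_a.start), str(lp.anchor_a.end),
                lp.anchor_b.chrom, str(lp.anchor_b.start), str(lp.anchor_b.end),
                ".", str(lp.read_count), repr(lp.fdr),
            ]) + "\n")


def _bed12_regions(start: int, thick_start: int, thick_end: int,
                   block_starts: list[int], block_sizes: list[int],
                   strand: str) -> dict[str, tuple[GenomicInterval, ...]]:
    """Split BED12 exon blocks into 5'UTR/CDS/3'UTR by the thick range."""
    utr_left, cds, utr_right = [], [], []
    for bs, sz in zip(block_starts, block_sizes):
        lo, hi = start + bs, start + bs + sz
        if lo < thick_start:
            utr_left.append((lo, min(hi, thick_start)))
        if max(lo, thick_start) < min(hi, thick_end):
            cds.append((max(lo, thick_start), min(hi, thick_end)))
        if hi > thick_end:
            utr_right.append((max(lo, thick_end), hi))
    five, three = (utr_left, utr_right) if strand == "+" else (utr_right, utr_left)
    return {"5UTR": five, "CDS": cds, "3UTR": three}


def read_gene_models(path: str | os.PathLike, format: str) -> GeneCatalog:
    """Read gene models from BED12 or GTF.

    TSS follows strand (start for ``+``, end-1 for ``-``).  GTF input must
    carry a ``gene_id`` attribute; region segments are assembled from
    ``five_prime_utr``/``CDS``/``three_prime_utr`` (or ``UTR``) features.
    """
    fmt = format.lower()
    if fmt == "bed12":
        return _read_bed12(path)
    if fmt == "gtf":
        return _read_gtf(path)
    raise ValueError(f"unknown gene-model format {format!r}")


def _read_bed12(path) -> GeneCatalog:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"BED12 needs 12 columns, got {len(f)}",
                                  path, lineno)
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name, strand = f[3], f[5]
                thick_start, thick_end = int(f[6]), int(f[7])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
                raw = _bed12_regions(start, thick_start, thick_end,
                                     starts, sizes, strand)
                regions = {lab: tuple(GenomicInterval(chrom, lo, hi)
                                      for lo, hi in ivs)
                           for lab, ivs in raw.items() if ivs}
                genes.append(GeneModel(name, chrom, strand, start, end, regions))
            except ValueError as exc:
                raise FormatError(str(exc), path, lineno) from exc
    return GeneCatalog(genes)


_GTF_REGION_MAP = {
    "five_prime_utr": "5UTR", "5utr": "5UTR", "utr5": "5UTR",
    "cds": "CDS",
    "three_prime_utr": "3UTR", "3utr": "3UTR", "utr3": "3UTR",
}


def _read_gtf(path) -> GeneCatalog:
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique",
                            disable_infer_genes=True,
                            disable_infer_transcripts=True)
    genes = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = g.attributes.get("gene_id", [g.id])[0]
        regions: dict[str, list[GenomicInterval]] = {}
        for child in db.children(g):
            label = _GTF_REGION_MAP.get(child.featuretype.lower())
            if label is None:
                continue
            # GTF is 1-based inclusive -> 0-based half-open
            regions.setdefault(label, []).append(
                GenomicInterval(child.seqid, child.start - 1, child.end))
        genes.append(GeneModel(
            gene_id, g.seqid, g.strand, g.start - 1, g.end,
            {k: tuple(sorted(v)) for k, v in regions.items()}))
    return GeneCatalog(genes)


def write_gene_models_gtf(catalog: GeneCatalog, path: str | os.PathLike) -> None:
    """Write a catalog as GTF (1-based inclusive), deterministically ordered."""
    inv = {"5UTR": "five_prime_utr", "CDS": "CDS", "3UTR": "three_prime_utr"}
    with open(path, "w", newline="\n") as fh:
        for g in catalog:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write("\t".join([g.chrom, "loopmet", "gene", str(g.start + 1),
                                str(g.end), ".", g.strand, ".", attrs]) + "\n")
            for label in REGION_LABELS:
                for iv in g.regions.get(label, ()):
                    fh.write("\t".join([
                        g.chrom, "loopmet", inv[label], str(iv.start + 1),
                        str(iv.end), ".", g.strand, ".", attrs]) + "\n")


#: declared table schemas: column name -> pandas dtype
EXPRESSION_SCHEMA = {"gene_id": str, "contrast": str, "score": float,
                     "log_fc": float, "padj": float}
M6A_PEAK_SCHEMA = {"transcript_id": str, "chrom": str, "start": int,
                   "end": int, "signal": float}
ISOTOPOLOGUE_KEY_SCHEMA = {"metabolite": str, "n_carbons": int,
                           "group": str, "replicate": int}
CT_SCHEMA = {"sample": str, "target": str, "target_ct": float,
             "reference_ct": float}


def read_table(path: str | os.PathLike, schema: Mapping[str, type],
               sep: str = ",", allow_extra: bool = True) -> pd.DataFrame:
    """Read a delimited table and validate it against a column schema.

    Raises :class:`FormatError` for a missing required column or a
    non-numeric cell in a numeric column.
    """
    # round_trip float parsing keeps read->write->read an identity
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for col, dtype in schema.items():
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}", path)
        try:
            df[col] = df[col].astype(dtype)
        except (ValueError, TypeError) as exc:
            raise FormatError(
                f"column {col!r} not convertible to {dtype.__name__}", path
            ) from exc
    if not allow_extra:
        extra = [c for c in df.columns if c not in schema]
        if extra:
            raise FormatError(f"unexpected columns {extra}", path)
    return df


def write_table(df: pd.DataFrame, path: str | os.PathLike,
                sep: str = ",") -> None:
    """Write a table deterministically (fixed column order, LF endings)."""
    df.to_csv(path, sep=sep, index=False, lineterminator="\n")


def validate_expression(df: pd.DataFrame) -> pd.DataFrame:
    """Check expression-table invariants (padj in [0,1], unique keys)."""
    bad = df[(df["padj"] < 0) | (df["padj"] > 1)]
    if len(bad):
        raise ValueError(f"padj outside [0, 1] for {len(bad)} records")
    dup = df.duplicated(subset=["gene_id", "contrast"])
    if dup.any():
        raise ValueError(
            f"duplicate (gene_id, contrast) records: "
            f"{df.loc[dup, 'gene_id'].tolist()[:5]}")
    return df
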