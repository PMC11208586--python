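import numpy as np
import pandas as pd
import pytest

from loopmet.genomic_io import GeneCatalog, GeneModel, GenomicInterval, Loop
from loopmet.synthetic import GeneratorConfig, generate_genome


def make_loop(chrom_a="chr1", start_a=1000, end_a=2000, chrom_b=None,
              start_b=4000, end_b=5000, reads=10, fdr=0.001,
              assay="H3K27Ac", condition="growing") -> Loop:
    return Loop(GenomicInterval(chrom_a, start_a, end_a),
                GenomicInterval(chrom_b or chrom_a, start_b, end_b),
                reads, fdr, assay=assay, condition=condition)


@pytest.fixture
def tiny_catalog() -> GeneCatalog:
    """Three well-separated genes on two chromosomes."""
    def gene(gid, chrom, strand, start, end):
        l5 = (end - start) // 10
        l3 = (end - start) // 5
        if strand == "+":
            segs = {"5UTR": (start, start + l5), "CDS": (start + l5, end - l3),
                    "3UTR": (end - l3, end)}
        else:
            segs = {"3UTR": (start, start + l3), "CDS": (start + l3, end - l5),
                    "5UTR": (end - l5, end)}
        regions = {k: (GenomicInterval(chrom, lo, hi),)
                   for k, (lo, hi) in segs.items()}
        return GeneModel(gid, chrom, strand, start, end, regions)

    return GeneCatalog([
        gene("gA", "chr1", "+", 10_000, 20_000),
        gene("gB", "chr1", "-", 50_000, 58_000),
        gene("gC", "chr2", "+", 30_000, 36_000),
    ])


@pytest.fixture(scope="session")
def default_bundle():
    """One default-scale synthetic genome shared across tests."""
    cfg = GeneratorConfig(seed=11)
    catalog, sizes = generate_genome(cfg)
    return cfg, catalog, sizes


def brute_force_ep(loops, promoters):
    """Independent all-pairs overlap oracle for EP assignment."""
    out = []
    for lp in loops:
        genes = set()
        for pw in promoters:
            for anchor in (lp.anchor_a, lp.anchor_b):
                if (anchor.chrom == pw.interval.chrom
                        and anchor.start < pw.interval.end
                        and pw.interval.start < anchor.end):
                    genes.add(pw.gene_id)
        out.append(frozenset(genes))
    return out
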