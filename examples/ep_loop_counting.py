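"""Count enhancer-promoter (EP) loops per gene in two conditions.

Builds a small synthetic genome with planted per-gene EP counts, filters
loops by the H3K27Ac significance rule (FDR < 0.01, >= 4 reads), assigns
them to promoter windows (TSS +/- 1 kb), and tabulates EP# and delta EP#.
"""

from loopmet import (GeneratorConfig, assign_ep, count_ep_per_gene,
                     define_promoters, distance_distribution,
                     filter_significant_loops, generate_genome,
                     generate_loops)

cfg = GeneratorConfig(seed=1, n_genes=100, n_background_loops=300)
catalog, sizes = generate_genome(cfg)
loops, truth = generate_loops(cfg, catalog, sizes)
promoters = define_promoters(catalog, flank=1000)

assignments = {}
for condition, raw in loops.items():
    significant = filter_significant_loops(raw, "H3K27Ac")
    print(f"{condition}: {len(raw)} loops, {len(significant)} significant")
    print(distance_distribution(significant).round(1))
    assignments[condition] = assign_ep(significant, promoters)

ep = count_ep_per_gene(assignments, catalog)
print("\nper-gene EP counts (delta = senescent - growing):")
print(ep.head(8).to_string(index=False))
agree = (ep.merge(truth, on="gene_id", suffixes=("", "_planted"))
         .eval("delta_ep == delta_ep_planted").mean())
print(f"\nfraction of genes whose delta EP# matches the planted truth: "
      f"{agree:.3f}")
# 1.000 means the EP stage recovered every planted contact change exactly.
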