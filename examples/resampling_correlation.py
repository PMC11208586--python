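"""Correlate contact changes with nascent transcription by grouped resampling.

Genes are grouped by delta EP#; 70 genes are drawn from each group 200
times and the mean log fold-change of each draw is averaged.  Pearson r
between group delta EP# and the grand means measures how tightly contact
gain tracks transcriptional activation, robust to outlier genes.
"""

import pandas as pd

from loopmet import (GeneratorConfig, generate_expression, generate_genome,
                     generate_loops, group_resample_logfc)

cfg = GeneratorConfig(seed=3, mtc_up_lfc=0.0)  # pure coupling, slope 0.05
catalog, sizes = generate_genome(cfg)
_, truth = generate_loops(cfg, catalog, sizes)
expression, _ = generate_expression(cfg, truth)

sen = expression[expression["contrast"] == "sen_vs_growing"]
result = group_resample_logfc(truth, sen.set_index("gene_id")["log_fc"],
                              group_size=70, reps=200, seed=3)
print(result.groups.round(4).to_string(index=False))
print(f"\nPearson r = {result.pearson_r:.4f}, two-sided p = "
      f"{result.p_value:.2e}")
# r near 1 with small p: the planted linear coupling (0.05 log2FC per loop
# gained) is recovered from the group grand means.
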