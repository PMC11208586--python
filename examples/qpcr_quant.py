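"""Comparative-Ct quantitation: 2^-ddCt fold changes, 3C ligation
frequencies, and translational efficiency."""

import pandas as pd

from loopmet import (CtMeasurement, ddct_fold_change, ligation_frequency,
                     translational_efficiency)

# expression fold change vs a calibrator sample, GAPDH-normalized
sample = CtMeasurement("senescent", target_ct=22.1, reference_ct=18.0)
calib = CtMeasurement("growing", target_ct=24.3, reference_ct=18.2)
fold = ddct_fold_change(sample, calib)
print(f"2^-ddCt fold change (senescent vs growing): {fold:.2f}")
# > 1 means the target is more abundant in the senescent sample.

# 3C-qPCR: relative ligation frequency per anchor-primer pair
panel = pd.DataFrame([
    ("sen", "HK2_enh1", 23.0, 18.0), ("sen", "HK2_enh2", 24.5, 18.0),
    ("sen", "NPC", 28.0, 18.0),
    ("grow", "HK2_enh1", 24.0, 18.0), ("grow", "HK2_enh2", 24.5, 18.0),
    ("grow", "NPC", 28.0, 18.0),
], columns=["sample", "pair", "target_ct", "reference_ct"])
freq = ligation_frequency(panel, calibrator_sample="grow", npc_pair="NPC")
print(freq[freq["sample"] == "sen"].to_string(index=False))
# frequency 2.0 for HK2_enh1: that contact ligates twice as often in
# senescent chromatin; the NPC (non-peak control) pair stays at background.

te = translational_efficiency(polysome_level=3.2, free_level=8.0)
print(f"translational efficiency (polysome/free): {te:.2f}")
# < 1 indicates the mRNA is depleted from polysomes relative to free mRNA.
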