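"""Comparative-Ct quantitation utilities shared by expression, 3C, and
polysome analyses: 2^-ddCt fold changes, 3C ligation frequencies, and
translational efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


def _geomean_ct(ct) -> float:
    """Geometric mean of one or several reference-gene Cts."""
    arr = np.atleast_1d(np.asarray(ct, float))
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("Ct values must be positive and finite")
    return float(np.exp(np.mean(np.log(arr))))


@dataclass(frozen=True)
class CtMeasurement:
    """Target and reference Cts for one sample.

    ``reference_ct`` may be a single value or a sequence of values from
    several reference genes; multiple references are combined by the
    geometric mean of their Cts before the delta.
    """

    sample: str
    target_ct: float
    reference_ct: float | Sequence[float]

    def __post_init__(self):
        if not np.isfinite(self.target_ct) or self.target_ct <= 0:
            raise ValueError("target_ct must be positive and finite")
        _geomean_ct(self.reference_ct)  # validates

    @property
    def delta_ct(self) -> float:
        return self.target_ct - _geomean_ct(self.reference_ct)


def ddct_fold_change(sample: CtMeasurement, calibrator: CtMeasurement) -> float:
    """Relative quantity by the 2^-ddCt method.

    ddCt = dCt(sample) - dCt(calibrator); identical measurements give
    exactly 1, and any constant shift of all Cts cancels.
    """
    ddct = sample.delta_ct - calibrator.delta_ct
    return float(2.0 ** (-ddct))


def ligation_frequency(panel: pd.DataFrame, calibrator_sample: str,
                       npc_pair: str | None = None) -> pd.DataFrame:
    """Comparative-Ct relative ligation frequency per 3C primer pair.

    ``panel`` columns: sample, pair, target_ct, reference_ct.  For each
    (sample, pair), the relative quantity is 2^-ddCt versus the same pair
    in the calibrator sample.  The non-peak control (NPC) pair, if named,
    is flagged in the output as the background reference; if absent a
    warning is attached and quantities are still returned.
    """
    required = {"sample", "pair", "target_ct", "reference_ct"}
    if not required <= set(panel.columns):
        raise ValueError(f"panel missing columns {required - set(panel.columns)}")
    cal = panel[panel["sample"] == calibrator_sample].set_index("pair")
    if cal.empty:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not in panel")
    rows = []
    for _, row in panel.iterrows():
        pair = row["pair"]
        meas = CtMeasurement(row["sample"], row["target_ct"], row["reference_ct"])
        if pair in cal.index:
            c = cal.loc[pair]
            calm = CtMeasurement(calibrator_sample, c["target_ct"],
                                 c["reference_ct"])
            freq = ddct_fold_change(meas, calm)
        else:
            freq = float("nan")
        rows.append({"sample": row["sample"], "pair": pair,
                     "ligation_frequency": freq,
                     "is_npc": pair == npc_pair})
    out = pd.DataFrame(rows)
    if npc_pair is not None and npc_pair not in set(panel["pair"]):
        import warnings
        warnings.warn(f"non-peak control pair {npc_pair!r} absent from panel")
    return out


def translational_efficiency(polysome_level: float, free_level: float) -> float:
    """Polysome-associated signal normalized to the free-mRNA level."""
    if free_level <= 0:
        raise ValueError("free mRNA level must be positive")
    return float(polysome_level) / float(free_level)


def translational_efficiency_table(levels: pd.DataFrame) -> pd.DataFrame:
    """Vectorized TE over a table with ``polysome_level``/``free_level``."""
    if (levels["free_level"] <= 0).any():
        raise ValueError("free mRNA levels must be positive")
    out = levels.copy()
    out["te"] = levels["polysome_level"] / levels["free_level"]
    return out
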