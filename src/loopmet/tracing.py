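"""13C-glucose isotopologue analysis.

Raw isotopologue intensities measured by LC-MS contain a contribution from
naturally occurring 13C (~1.07% of carbon).  Correction deconvolves that
contribution: the measured vector is modeled as the true mass-isotopomer
distribution (MID) convolved with a binomial natural-abundance kernel, and
the MID is recovered by non-negative least squares.  Labeled fractions
(e.g. M+5 for purines synthesized from 13C6-glucose-derived ribose) feed a
three-criterion screen across the five experimental groups:

  a) more extensive labeling in senescent (shControl) than control cells;
  b) decreased labeling in senescent cells on HK2 knockdown;
  c) the decrease rescued by wildtype HK2 but not by catalytically dead
     mutant HK2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: natural abundance of 13C
DEFAULT_P13C = 0.0107

#: canonical group labels of the five-arm tracing design
GROUP_CONTROL = "control"            # proliferating, shControl
GROUP_SEN = "sen_shControl"          # senescent, shControl
GROUP_SHHK2 = "sen_shHK2"            # senescent, HK2 knockdown
GROUP_WT = "sen_shHK2_WT"            # knockdown rescued with wildtype HK2
GROUP_MUT = "sen_shHK2_mut"          # knockdown rescued with mutant HK2
ALL_GROUPS = (GROUP_CONTROL, GROUP_SEN, GROUP_SHHK2, GROUP_WT, GROUP_MUT)


def natural_abundance_matrix(n_carbons: int, p13c: float = DEFAULT_P13C) -> np.ndarray:
    """Lower-triangular carbon natural-abundance correction matrix.

    Column k (the species with k tracer-labeled carbons) holds the binomial
    mass distribution of the remaining n-k carbons, shifted down by k rows;
    every column sums to 1.  With p13c=0 this is the identity.
    """
    if not 0 <= p13c < 1:
        raise ValueError("p13c must be in [0, 1)")
    n = int(n_carbons)
    A = np.zeros((n + 1, n + 1))
    for k in range(n + 1):
        pmf = stats.binom.pmf(np.arange(n - k + 1), n - k, p13c)
        A[k:, k] = pmf
    return A


def correct_mid(raw: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Recover the MID from raw intensities by non-negative least squares.

    NNLS (rather than plain inversion) keeps fractions non-negative on
    noisy data; on noise-free input it coincides with inversion.  The
    solution is normalized to sum to 1.
    """
    raw = np.asarray(raw, float)
    if raw.ndim != 1 or raw.size != matrix.shape[0]:
        raise ValueError("raw length does not match correction matrix")
    if np.any(raw < 0):
        raise ValueError("raw intensities must be non-negative")
    if raw.sum() == 0:
        raise ValueError("all-zero raw vector: no signal to correct")
    x, _ = optimize.nnls(matrix, raw)
    total = x.sum()
    if total == 0:
        raise ValueError("correction produced an all-zero MID")
    return x / total


def labeled_fraction(corrected_mid: np.ndarray, m: int) -> float:
    """Fractional abundance of the M+m species of a corrected MID."""
    mid = np.asarray(corrected_mid, float)
    if not 0 <= m < mid.size:
        raise ValueError(f"m={m} out of range for {mid.size - 1} carbons")
    return float(mid[m])


def normalize_to_protein(intensity, protein_conc: float):
    """Scale intensities by the protein concentration of the extract pellet."""
    if protein_conc <= 0:
        raise ValueError("protein concentration must be positive")
    return np.asarray(intensity, float) / protein_conc


@dataclass
class ScreenConfig:
    alpha: float = 0.05
    equal_var: bool = True       # classic two-tailed Student's t; False = Welch
    effect_size_gate: bool = False  # additionally require mutant mean below
    # the midpoint of shHK2 and WT means for criterion c


def screen_metabolites(fractions: pd.DataFrame, alpha: float = 0.05,
                       equal_var: bool = True,
                       effect_size_gate: bool = False) -> pd.DataFrame:
    """Three-criterion screen over labeled fractions.

    ``fractions`` columns: metabolite, group, replicate, fraction, with the
    five canonical groups and >= 2 replicates each.  Per metabolite:

    - criterion_a: mean(sen_shControl) > mean(control), two-tailed t p < alpha
    - criterion_b: mean(sen_shHK2) < mean(sen_shControl), p < alpha
    - criterion_c: mean(WT rescue) > mean(sen_shHK2) with p < alpha AND the
      mutant rescue NOT significantly above sen_shHK2 (p >= alpha or wrong
      direction); the optional effect-size gate further requires the mutant
      mean below the shHK2/WT midpoint.

    Metabolites missing a group are flagged untestable and never pass.
    Output order and values are invariant to input row order.
    """
    rows = []
    for met, sub in fractions.groupby("metabolite", sort=True):
        vals = {g: sub.loc[sub["group"] == g, "fraction"].to_numpy(float)
                for g in ALL_GROUPS}
        missing = [g for g in ALL_GROUPS if vals[g].size < 2]
        if missing:
            rows.append({"metabolite": met, "testable": False,
                         "criterion_a": False, "criterion_b": False,
                         "criterion_c": False, "p_a": np.nan, "p_b": np.nan,
                         "p_c_wt": np.nan, "p_c_mut": np.nan,
                         "passes_all": False})
            continue

        def _t(g1, g2):
            return float(stats.ttest_ind(vals[g1], vals[g2],
                                         equal_var=equal_var).pvalue)

        p_a = _t(GROUP_SEN, GROUP_CONTROL)
        a = vals[GROUP_SEN].mean() > vals[GROUP_CONTROL].mean() and p_a < alpha
        p_b = _t(GROUP_SHHK2, GROUP_SEN)
        b = vals[GROUP_SHHK2].mean() < vals[GROUP_SEN].mean() and p_b < alpha
        p_wt = _t(GROUP_WT, GROUP_SHHK2)
        wt_ok = vals[GROUP_WT].mean() > vals[GROUP_SHHK2].mean() and p_wt < alpha
        p_mut = _t(GROUP_MUT, GROUP_SHHK2)
        mut_rescues = (vals[GROUP_MUT].mean() > vals[GROUP_SHHK2].mean()
                       and p_mut < alpha)
        c = wt_ok and not mut_rescues
        if c and effect_size_gate:
            midpoint = (vals[GROUP_SHHK2].mean() + vals[GROUP_WT].mean()) / 2
            c = vals[GROUP_MUT].mean() < midpoint
        rows.append({"metabolite": met, "testable": True,
                     "criterion_a": bool(a), "criterion_b": bool(b),
                     "criterion_c": bool(c), "p_a": p_a, "p_b": p_b,
                     "p_c_wt": p_wt, "p_c_mut": p_mut,
                     "passes_all": bool(a and b and c)})
    return pd.DataFrame(rows)


def correct_isotopologue_table(table: pd.DataFrame,
                               p13c: float = DEFAULT_P13C) -> pd.DataFrame:
    """Correct a long-form raw isotopologue table and add labeled fractions.

    ``table`` columns: metabolite, n_carbons, group, replicate, plus
    M+0...M+n intensity columns (extra M+ columns beyond n_carbons may be
    absent).  Returns the same keys with corrected ``mid_0...mid_n``
    columns summing to 1 per row.
    """
    out_rows = []
    matrices: dict[int, np.ndarray] = {}
    for _, row in table.iterrows():
        n = int(row["n_carbons"])
        if n not in matrices:
            matrices[n] = natural_abundance_matrix(n, p13c)
        raw = np.array([row[f"M+{i}"] for i in range(n + 1)], float)
        mid = correct_mid(raw, matrices[n])
        rec = {k: row[k] for k in ("metabolite", "n_carbons", "group",
                                   "replicate")}
        rec.update({f"mid_{i}": mid[i] for i in range(n + 1)})
        out_rows.append(rec)
    return pd.DataFrame(out_rows)


def labeled_fraction_table(corrected: pd.DataFrame, m_by_metabolite,
                           ) -> pd.DataFrame:
    """Extract the screened M+m fraction per metabolite/group/replicate.

    ``m_by_metabolite`` maps metabolite name to the isotopologue index of
    interest (e.g. 5 for purine M+5); an integer applies to all.
    """
    rows = []
    for _, row in corrected.iterrows():
        met = row["metabolite"]
        m = m_by_metabolite if isinstance(m_by_metabolite, int) \
            else m_by_metabolite[met]
        rows.append({"metabolite": met, "group": row["group"],
                     "replicate": row["replicate"],
                     "fraction": float(row[f"mid_{m}"])})
    return pd.DataFrame(rows)
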