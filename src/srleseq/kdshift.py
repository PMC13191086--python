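"""Knockdown-induced localization shifts.

For each gene, the nuclear:cytoplasmic log2 ratio is computed per replicate
(CPM with pseudocount, nuclear and cytoplasmic samples paired by replicate
index) in both the control and knockdown condition.  The shift statistic is
delta = mean ratio in knockdown minus mean ratio in control, tested by a
two-sample two-sided Student t-test on the per-replicate ratios.  A gene
shifts to the nucleus when delta > 0.58 with p < 0.05, to the cytoplasm when
delta < -0.58 with p < 0.05 (both inequalities strict).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .counts import CYTOPLASMIC, NUCLEAR, CountTable
from .enrichment import cpm


def _replicate_ratios(table: CountTable, pseudocount: float) -> np.ndarray:
    """Per-gene per-replicate log2(cpm_nuc + c)/(cpm_cyt + c), paired by replicate id."""
    C = cpm(table)
    nuc = {s.replicate: j for j, s in enumerate(table.samples) if s.fraction == NUCLEAR}
    cyt = {s.replicate: j for j, s in enumerate(table.samples) if s.fraction == CYTOPLASMIC}
    reps = sorted(set(nuc) & set(cyt))
    if len(reps) < 2:
        raise ValueError("need >= 2 paired replicates per fraction")
    cols = [
        np.log2((C[:, nuc[r]] + pseudocount) / (C[:, cyt[r]] + pseudocount)) for r in reps
    ]
    return np.column_stack(cols)


def shift_test(
    ctrl: CountTable,
    kd: CountTable,
    delta_cut: float = 0.58,
    p_cut: float = 0.05,
    pseudocount: float = 0.5,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-gene localization shift between knockdown and control.

    Returns a DataFrame indexed by gene with lfc_ctrl, lfc_kd, delta,
    p_value and shift_class.  ``equal_var=False`` switches to Welch's test.
    """
    if ctrl.elements != kd.elements:
        extra = sorted(set(ctrl.elements) ^ set(kd.elements))[:10]
        raise ValueError(f"gene sets differ between conditions; offenders include {extra}")
    r_ctrl = _replicate_ratios(ctrl, pseudocount)
    r_kd = _replicate_ratios(kd, pseudocount)
    lfc_ctrl = r_ctrl.mean(axis=1)
    lfc_kd = r_kd.mean(axis=1)
    delta = lfc_kd - lfc_ctrl
    _t, p = stats.ttest_ind(r_kd, r_ctrl, axis=1, equal_var=equal_var)
    cls = np.full(len(delta), "none", dtype=object)
    cls[(delta > delta_cut) & (p < p_cut)] = "to_nuclear"
    cls[(delta < -delta_cut) & (p < p_cut)] = "to_cytoplasm"
    return pd.DataFrame(
        {
            "lfc_ctrl": lfc_ctrl,
            "lfc_kd": lfc_kd,
            "delta": delta,
            "p_value": p,
            "shift_class": cls,
        },
        index=pd.Index(ctrl.elements, name="gene_id"),
    )


def volcano_table(
    records: pd.DataFrame, n_bins: int = 50
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Volcano plotting data: per-gene (delta, -log10 p, class) plus a binned
    2-D density grid.  No rendering; downstream plotting consumes the tables."""
    if records.empty:
        empty = pd.DataFrame(columns=["delta", "neg_log10_p", "shift_class"])
        grid = pd.DataFrame(columns=["delta_bin_left", "p_bin_left", "count"])
        return empty, grid
    pts = pd.DataFrame(
        {
            "delta": records["delta"],
            "neg_log10_p": -np.log10(np.clip(records["p_value"], 1e-300, None)),
            "shift_class": records["shift_class"],
        },
        index=records.index,
    )
    H, xe, ye = np.histogram2d(pts["delta"], pts["neg_log10_p"], bins=n_bins)
    xs, ys = np.nonzero(H)
    grid = pd.DataFrame(
        {
            "delta_bin_left": xe[xs],
            "p_bin_left": ye[ys],
            "count": H[xs, ys].astype(int),
        }
    )
    return pts, grid
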