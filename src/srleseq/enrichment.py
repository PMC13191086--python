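"""Nuclear-retention scoring and differential count testing.

The nuclear retention score (NRS) of an element is the log2 ratio of its mean
CPM in the nuclear fraction to its mean CPM in the cytoplasmic fraction
(pseudocount-guarded).  Significance comes from a negative-binomial Wald test
across replicates: median-of-ratios size factors, moment-based dispersion
moderated toward the central value, a delta-method standard error for the
log2 fold change, two-sided normal p-values, and Benjamini-Hochberg
adjustment.  Elements are called nuclear-enriched at NRS >= 0.58 with
p < 0.05, cytoplasm-enriched at NRS <= -0.58 with p < 0.05.

The 0.58 cut is log2(1.5) truncated to two decimals: a 1.5-fold change in
the nuclear:cytoplasmic CPM ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .counts import CYTOPLASMIC, NUCLEAR, CountTable

LOG2 = np.log(2.0)

#: Prior degrees of freedom pulling per-element dispersions toward the
#: central value.  With triplicate fractions the residual df is 4, so the
#: moderated estimate is dominated by the library-wide dispersion, which
#: keeps the normal-reference Wald test calibrated.
DISPERSION_PRIOR_DF = 20.0
DISPERSION_FLOOR = 1e-8


@dataclass(frozen=True)
class TestConfig:
    """Thresholds and zero-handling for enrichment calling."""

    nrs_cut: float = 0.58
    p_cut: float = 0.05
    pseudocount: float = 0.5
    use_adjusted_p: bool = False

    def __post_init__(self) -> None:
        if self.nrs_cut <= 0:
            raise ValueError("nrs_cut must be positive")
        if not 0 < self.p_cut < 1:
            raise ValueError("p_cut must be in (0, 1)")


def cpm(table: CountTable) -> np.ndarray:
    """Counts per million: each column scaled to sum to 1e6."""
    depths = table.counts.sum(axis=0)
    zero = np.flatnonzero(depths == 0)
    if zero.size:
        names = ", ".join(table.sample_names[j] for j in zero)
        raise ValueError(f"zero sequencing depth in sample(s): {names}")
    return table.counts * (1e6 / depths)


def compute_nrs(cpm_nuc, cpm_cyt, pseudocount: float = 0.5):
    """log2((cpm_nuc + c) / (cpm_cyt + c)); antisymmetric under fraction swap."""
    cpm_nuc = np.asarray(cpm_nuc, dtype=float)
    cpm_cyt = np.asarray(cpm_cyt, dtype=float)
    if np.any(cpm_nuc < 0) or np.any(cpm_cyt < 0):
        raise ValueError("CPM values must be non-negative")
    return np.log2((cpm_nuc + pseudocount) / (cpm_cyt + pseudocount))


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors against the geometric-mean pseudo-reference.

    Elements with any zero count are excluded from the reference set; if no
    element is all-positive the fallback is depth-proportional factors.
    """
    K = np.asarray(counts, dtype=float)
    positive = np.all(K > 0, axis=1)
    if not positive.any():
        depths = K.sum(axis=0)
        return depths / stats.gmean(depths)
    logK = np.log(K[positive])
    ref = logK.mean(axis=1)
    return np.exp(np.median(logK - ref[:, None], axis=0))


def _moderated_dispersion(
    Z: np.ndarray, idx_nuc: np.ndarray, idx_cyt: np.ndarray, inv_s_mean: float
) -> np.ndarray:
    """Moment dispersion per element, pulled toward the library-wide mean.

    The moment estimate subtracts the Poisson (counting) variance from the
    pooled within-fraction variance of normalized counts; the excess relative
    to the squared mean is the dispersion.  Per-element estimates at few
    residual df are noisy enough to break Wald calibration, so they are
    linearly blended with the central value at ``DISPERSION_PRIOR_DF``.
    """
    n1, n2 = len(idx_nuc), len(idx_cyt)
    v1 = Z[:, idx_nuc].var(axis=1, ddof=1)
    v2 = Z[:, idx_cyt].var(axis=1, ddof=1)
    vp = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    mu = (Z[:, idx_nuc].mean(axis=1) * n1 + Z[:, idx_cyt].mean(axis=1) * n2) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (vp - mu * inv_s_mean) / mu**2
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)
    well_covered = mu >= 5.0
    central = float(alpha[well_covered].mean()) if well_covered.any() else float(alpha.mean())
    d_res = n1 + n2 - 2
    moderated = (d_res * alpha + DISPERSION_PRIOR_DF * central) / (d_res + DISPERSION_PRIOR_DF)
    return np.maximum(moderated, DISPERSION_FLOOR)


def nb_wald_test(table: CountTable, pseudocount: float = 0.5) -> pd.DataFrame:
    """Negative-binomial Wald test of nuclear vs cytoplasmic counts per element.

    Returns a DataFrame indexed by element with columns ``log2fc_test``,
    ``wald_stat``, ``p_value``, ``p_adjusted``.  Requires >= 2 replicates in
    each fraction.
    """
    idx_nuc = table.columns(NUCLEAR)
    idx_cyt = table.columns(CYTOPLASMIC)
    if len(idx_nuc) < 2 or len(idx_cyt) < 2:
        raise ValueError("nb_wald_test needs >= 2 replicates per fraction")
    s = size_factors(table.counts)
    Z = table.counts / s
    inv_s_mean = float(np.mean(1.0 / s))
    alpha = _moderated_dispersion(Z, idx_nuc, idx_cyt, inv_s_mean)

    m_nuc = Z[:, idx_nuc].mean(axis=1)
    m_cyt = Z[:, idx_cyt].mean(axis=1)
    lfc = np.log2((m_nuc + pseudocount) / (m_cyt + pseudocount))

    # delta method: Var(log2 mean) = Var(mean) / ((mean + c)^2 * ln(2)^2)
    def _var_log2(m: np.ndarray, idx: np.ndarray) -> np.ndarray:
        inv_s = float(np.mean(1.0 / s[idx]))
        var_mean = (m * inv_s + alpha * m**2) / len(idx)
        return var_mean / ((m + pseudocount) ** 2 * LOG2**2)

    se = np.sqrt(_var_log2(m_nuc, idx_nuc) + _var_log2(m_cyt, idx_cyt))
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(wald))
    padj = false_discovery_control_bh(p)
    return pd.DataFrame(
        {
            "log2fc_test": lfc,
            "wald_stat": wald,
            "p_value": p,
            "p_adjusted": padj,
        },
        index=pd.Index(table.elements, name="element"),
    )


def false_discovery_control_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (one family, both directions)."""
    return stats.false_discovery_control(np.clip(p, 0.0, 1.0), method="bh")


def score_elements(table: CountTable, config: TestConfig = TestConfig()) -> pd.DataFrame:
    """Full per-element scoring: CPMs, NRS, Wald test, enrichment class.

    Columns: cpm_nuclear, cpm_cytoplasmic, nrs, log2fc_test, wald_stat,
    p_value, p_adjusted, enrichment_class.
    """
    C = cpm(table)
    idx_nuc = table.columns(NUCLEAR)
    idx_cyt = table.columns(CYTOPLASMIC)
    cpm_nuc = C[:, idx_nuc].mean(axis=1)
    cpm_cyt = C[:, idx_cyt].mean(axis=1)
    nrs = compute_nrs(cpm_nuc, cpm_cyt, config.pseudocount)
    test = nb_wald_test(table, pseudocount=config.pseudocount)
    df = pd.DataFrame(
        {
            "cpm_nuclear": cpm_nuc,
            "cpm_cytoplasmic": cpm_cyt,
            "nrs": nrs,
        },
        index=pd.Index(table.elements, name="element"),
    ).join(test)
    return classify_elements(df, config)


def classify_elements(records: pd.DataFrame, config: TestConfig = TestConfig()) -> pd.DataFrame:
    """Assign enrichment classes from NRS and p-values.

    Nuclear iff nrs >= nrs_cut and p < p_cut; cytoplasmic iff
    nrs <= -nrs_cut and p < p_cut; otherwise neutral.  Boundary handling is
    inclusive on the NRS cut and strict on the p cut.
    """
    p = records["p_adjusted" if config.use_adjusted_p else "p_value"].to_numpy()
    nrs = records["nrs"].to_numpy()
    cls = np.full(len(records), "neutral", dtype=object)
    cls[(nrs >= config.nrs_cut) & (p < config.p_cut)] = NUCLEAR
    cls[(nrs <= -config.nrs_cut) & (p < config.p_cut)] = CYTOPLASMIC
    out = records.copy()
    out["enrichment_class"] = cls
    return out


def write_scores_tsv(df: pd.DataFrame, path, config: TestConfig = TestConfig()) -> None:
    """Write the per-element score table with run parameters as # header lines."""
    with open(path, "w") as fh:
        fh.write(f"# nrs_cut={config.nrs_cut} p_cut={config.p_cut} "
                 f"pseudocount={config.pseudocount} use_adjusted_p={config.use_adjusted_p}\n")
        df.to_csv(fh, sep="\t")


def composition_contrast(set_a: list[str], set_b: list[str]) -> pd.DataFrame:
    """Base-composition contrast between two equal-length element sets.

    Pools base counts within each set and, for each base, runs a 2x2 Fisher
    exact test (base vs not-base, set A vs set B).  Returns a DataFrame
    indexed by base with per-set frequencies, their difference, and the
    Fisher p-value; GC fractions are attached as ``df.attrs['gc_a']`` and
    ``df.attrs['gc_b']``.
    """
    if not set_a or not set_b:
        raise ValueError("both sets must be non-empty")
    lens = {len(s) for s in set_a} | {len(s) for s in set_b}
    if len(lens) != 1:
        raise ValueError("all elements must have equal length")

    def _base_counts(seqs: list[str]) -> dict[str, int]:
        pooled = "".join(seqs)
        return {b: pooled.count(b) for b in "ACGT"}

    ca, cb = _base_counts(set_a), _base_counts(set_b)
    na, nb = sum(ca.values()), sum(cb.values())
    rows = []
    for base in "ACGT":
        _odds, p = stats.fisher_exact(
            [[ca[base], na - ca[base]], [cb[base], nb - cb[base]]]
        )
        rows.append(
            {
                "base": base,
                "freq_a": ca[base] / na,
                "freq_b": cb[base] / nb,
                "diff": ca[base] / na - cb[base] / nb,
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows).set_index("base")
    df.attrs["gc_a"] = (ca["G"] + ca["C"]) / na
    df.attrs["gc_b"] = (cb["G"] + cb["C"]) / nb
    return df
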