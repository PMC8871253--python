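"""Group-comparison statistics and the smile-plot table.

Continuous features are compared with the pooled-variance Student
t-test (Welch available via ``equal_var=False``), p-values are adjusted
with the Benjamini-Hochberg step-up procedure, categorical 2x2 tables
use the Yates-corrected chi-square, and normality is assessed with the
D'Agostino-Pearson omnibus K^2 test.  The smile table pairs each
feature's -log10 adjusted p with its log2 fold change (HTN over NC, on
the raw feature scale).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DataError, ParameterError

__all__ = [
    "normality",
    "ttest_summary",
    "bh_fdr",
    "chi2_test",
    "smile_table",
]


def normality(values: np.ndarray) -> tuple[float, float]:
    """D'Agostino-Pearson omnibus test of normality.

    Combines the skewness and kurtosis z-scores into K^2, referred to a
    chi-square with 2 df.  Undefined below n = 20.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 20:
        raise DataError("D'Agostino-Pearson test requires n >= 20")
    k2, p = sps.normaltest(v)
    return float(k2), float(p)


def ttest_summary(mean1: float, sd1: float, n1: int,
                  mean2: float, sd2: float, n2: int,
                  equal_var: bool = True) -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics.

    Pooled-variance Student t by default (df = n1 + n2 - 2); set
    ``equal_var=False`` for Welch.  Returns ``(t, df, p)``.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ParameterError("SDs must be > 0")
    if n1 < 2 or n2 < 2:
        raise ParameterError("need n >= 2 per group")
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var)
    if equal_var:
        df = float(n1 + n2 - 2)
    else:
        va, vb = sd1**2 / n1, sd2**2 / n2
        df = (va + vb) ** 2 / (va**2 / (n1 - 1) + vb**2 / (n2 - 1))
    return float(res.statistic), df, float(res.pvalue)


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def chi2_test(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Yates-corrected Pearson chi-square on the 2x2 table [[a, b], [c, d]].

    Returns ``(chi2, p)`` with 1 df.  All four margins must be > 0.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ParameterError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DataError("zero margin in the 2x2 table")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=True)
    return float(chi2), float(p)


def smile_table(feature_table: pd.DataFrame, labels: np.ndarray,
                positive: int = 1, fdr_level: float = 0.05,
                fc_cutoff: float = 2.0, equal_var: bool = True) -> pd.DataFrame:
    """Per-feature group comparison with fold change and adjusted p.

    Must be given *raw* (un-autoscaled) feature values: the fold change
    ``FC = mean_HTN / mean_NC`` is only meaningful on the original
    scale.  The "change of at least ``fc_cutoff``-fold" flag reads the
    threshold two-sidedly (FC >= cutoff or FC <= 1/cutoff).  Features
    with a non-positive class mean get ``fc_defined = False`` and no FC
    flag.  NaN feature columns yield NaN statistics (screened upstream).

    Returns a DataFrame indexed by feature with columns: ``mean_htn,
    sd_htn, mean_nc, sd_nc, t, p_raw, p_fdr, fc, log2_fc,
    neg_log10_p_fdr, fc_defined, flag_fc, flag_sig, flagged``.
    """
    X = pd.DataFrame(feature_table)
    y = np.asarray(labels)
    pos = y == positive
    if pos.all() or (~pos).all():
        raise DataError("both classes must be present")
    A = X.loc[pos].to_numpy(dtype=float)
    B = X.loc[~pos].to_numpy(dtype=float)
    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    sd_a = A.std(axis=0, ddof=1)
    sd_b = B.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(A, B, axis=0, equal_var=equal_var)
    p = np.where(np.isnan(p), 1.0, p)  # degenerate columns: no evidence
    p_adj = bh_fdr(p)
    fc_defined = (mean_a > 0) & (mean_b > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.where(fc_defined, mean_a / mean_b, np.nan)
        log2_fc = np.log2(fc)
    flag_fc = fc_defined & ((fc >= fc_cutoff) | (fc <= 1.0 / fc_cutoff))
    flag_sig = p_adj < fdr_level
    out = pd.DataFrame(
        {
            "mean_htn": mean_a, "sd_htn": sd_a,
            "mean_nc": mean_b, "sd_nc": sd_b,
            "t": t, "p_raw": p, "p_fdr": p_adj,
            "fc": fc, "log2_fc": log2_fc,
            "neg_log10_p_fdr": -np.log10(np.maximum(p_adj, 1e-300)),
            "fc_defined": fc_defined,
            "flag_fc": flag_fc,
            "flag_sig": flag_sig,
            "flagged": flag_fc & flag_sig,
        },
        index=X.columns,
    )
    return out
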