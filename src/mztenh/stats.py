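"""Shared statistical routines.

One tested implementation of each test used across the package: the
two-sided Wilcoxon rank-sum test (exact for small samples, normal
approximation with tie correction otherwise), Pearson chi-squared on
contingency tables, Fisher's exact test, and Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["rank_sum_test", "chi2_contingency_test", "fisher_exact_test", "bh_fdr"]


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when the combined sample size is
    at most 20 and there are no ties; otherwise the normal approximation
    with tie correction (no continuity correction).

    Returns
    -------
    (statistic, pvalue) : the Mann-Whitney U of the first sample and the
    two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if x.size + y.size <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def chi2_contingency_test(table) -> tuple[float, int, float]:
    """Pearson chi-squared on an r x c contingency table, no continuity
    correction. Returns (statistic, dof, pvalue)."""
    table = np.asarray(table, dtype=float)
    chi2, p, dof, expected = sps.chi2_contingency(table, correction=False)
    if (expected < 1).any():
        import warnings

        warnings.warn("chi-squared table has expected cell count < 1",
                      stacklevel=2)
    return float(chi2), int(dof), float(p)


def fisher_exact_test(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns (odds_ratio, pvalue)."""
    odds, p = sps.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(odds), float(p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q
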