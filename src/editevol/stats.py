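"""Shared statistical kernels.

Thin, strictly-defined wrappers around scipy/statsmodels so every stage
uses one implementation of each test.  Sidedness and tie conventions:

* Fisher's exact test is two-sided, summing all tables with point
  probability <= that of the observed table (ties included).
* Benjamini-Hochberg is the step-up procedure with monotonicity
  enforced by a cumulative minimum from the largest p-value.
* Spearman's rho uses mid-ranks and the Pearson formula, so heavy ties
  (e.g. many sites at level 0) are handled.
* The Mann-Whitney U test is exact for small tie-free samples and uses
  the tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fisher_exact",
    "bh_adjust",
    "binomial_upper_tail",
    "binomial_two_sided",
    "rank_group_test",
    "ks_two_sample",
    "spearman_rho",
]


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table."""
    return float(_st.fisher_exact(np.asarray(table, dtype=int))[1])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def binomial_upper_tail(alt_reads: int, coverage: int, error_rate: float = 0.01) -> float:
    """One-sided exact binomial P(X >= alt | n=coverage, p=error_rate).

    Used to ask whether an observed A-to-G count exceeds the typical
    sequencing error rate.  Undefined (ValueError) for zero coverage.
    """
    if coverage <= 0:
        raise ValueError("binomial test undefined for zero coverage")
    if not 0 <= alt_reads <= coverage:
        raise ValueError("alt reads must lie in [0, coverage]")
    return float(_st.binomtest(alt_reads, coverage, error_rate, alternative="greater").pvalue)


def binomial_two_sided(k: int, n: int, p: float = 0.5) -> float:
    """Two-sided exact binomial test of k successes in n trials."""
    if n == 0:
        raise ValueError("binomial test undefined for n = 0")
    return float(_st.binomtest(k, n, p, alternative="two-sided").pvalue)


def rank_group_test(a, b, paired: bool = False) -> float:
    """Two-sided rank test between two groups.

    Unpaired: Mann-Whitney U (exact when both groups have <= 25
    tie-free values, tie-corrected normal approximation otherwise).
    Paired: Wilcoxon signed-rank on the differences.

    Degenerate inputs where every comparison ties return p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal-length groups")
        diffs = a - b
        if np.all(diffs == 0):
            return 1.0
        return float(_st.wilcoxon(a, b, zero_method="wilcox").pvalue)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(a.size, b.size) <= 25 and not has_ties) else "asymptotic"
    return float(_st.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    Returns (D, p) where D is the maximum ECDF distance and p comes
    from the asymptotic KS distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = _st.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def spearman_rho(a, b) -> float:
    """Spearman's rho via mid-ranks + Pearson correlation.

    NaN when either vector is constant in rank.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("vectors must have equal length")
    if a.size < 2:
        return float("nan")
    ra = _st.rankdata(a)
    rb = _st.rankdata(b)
    if np.all(ra == ra[0]) or np.all(rb == rb[0]):
        return float("nan")
    return float(np.corrcoef(ra, rb)[0, 1])
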