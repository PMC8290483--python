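"""Shared statistical helpers: rank-sum testing and p-value adjustment."""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXACT_MAX_N = 12


def ranksum_test(x, y) -> tuple[float, float]:
    """Two-sided two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when both groups have <= 12
    observations and there are no ties across the pooled sample; otherwise
    the normal approximation with tie and continuity corrections.  When the
    U statistic sits exactly at the null center (n1*n2/2) the two-sided
    p-value is 1 by symmetry.

    Returns ``(u_statistic, p_value)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N and tie_free:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    u, p = float(res.statistic), float(res.pvalue)
    if u == x.size * y.size / 2.0:
        p = 1.0
    return u, min(p, 1.0)


def bonferroni(pvals) -> np.ndarray:
    """min(1, p * m) for m comparisons."""
    p = np.asarray(pvals, dtype=float)
    return np.minimum(1.0, p * p.size)


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
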