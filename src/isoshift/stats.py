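"""Shared statistical helpers: rank tests, BH correction, binomial CIs."""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["rank_test", "bh_adjust", "binomial_ci"]

#: both groups at or below this size use the exact U null distribution
EXACT_MAX_N = 50


def rank_test(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of two samples.

    Uses the exact null distribution when both groups have at most
    ``EXACT_MAX_N`` observations and the pooled sample is tie-free, and the
    normal approximation with tie and continuity correction otherwise.
    Returns ``(U, p)`` with U counted for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_test requires two non-empty samples")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def binomial_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) two-sided binomial confidence interval."""
    if not 0 <= k <= n or n == 0:
        raise ValueError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    alpha = 1.0 - conf
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)
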