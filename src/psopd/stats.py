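"""Shared statistical primitives: BH adjustment, Welch tests, Kruskal-Wallis.

These are thin, validated wrappers over scipy/statsmodels so every stage of
the pipeline applies the same conventions (two-sided tests, explicit handling
of degenerate zero-variance cells, deterministic tie-breaking).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "adjust_fdr",
    "welch_from_stats",
    "kruskal_wallis",
    "significance_stars",
]


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    Parameters
    ----------
    p_values : array-like of float in [0, 1]

    Returns
    -------
    ndarray of q-values in the original input order. Invariant to input
    permutation; monotone nondecreasing when sorted by p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1] and be non-missing")
    return multipletests(p, method="fdr_bh")[1]


def welch_from_stats(mean1, var1, n1, mean2, var2, n2):
    """Welch two-sample t-test from summary statistics.

    Returns ``(t, df, p)`` with Satterthwaite degrees of freedom and a
    two-sided p-value.

    Degenerate conventions (both groups with zero variance): equal means give
    p = 1.0; unequal means give t = +/-inf, p = 0.0 — callers should flag
    such cells rather than trust the asymptotics.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("Welch test needs n >= 2 in both groups")
    if var1 < 0 or var2 < 0:
        raise ValueError("variances must be nonnegative")
    se1, se2 = var1 / n1, var2 / n2
    denom = se1 + se2
    diff = mean1 - mean2
    if denom == 0.0:
        if diff == 0.0:
            return 0.0, float(n1 + n2 - 2), 1.0
        return float(np.sign(diff) * np.inf), float(n1 + n2 - 2), 0.0
    t = diff / np.sqrt(denom)
    # Satterthwaite approximation
    df = denom**2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def kruskal_wallis(groups):
    """Kruskal-Wallis H with tie correction and chi-square p-value.

    ``groups`` is a sequence of 1-D arrays (>= 2 groups, each n >= 2).
    All-identical values across every group return (0.0, 1.0) by convention.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two observations")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star annotation.

    ``***`` p < .001, ``**`` p < .01, ``*`` p < .05, else ``ns``.
    """
    if not (0 <= p <= 1):
        raise ValueError("p must be in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
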