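"""Exact tests and multiple-testing helpers shared across the pipeline."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

# Relative tolerance for probability ties in the two-sided Fisher sum; the
# standard convention (shared with R's fisher.test) guards against tables
# whose tied point probabilities differ only in floating-point rounding.
_TIE_RTOL = 1e-7


def fisher_pvalues_for_margins(n: int, row1: int, col1: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Fisher exact p-values for every table with the given
    margins (grand total ``n``, first-row total ``row1``, first-column
    total ``col1``).

    Returns the support of the top-left cell and the matching p-values,
    each the sum of hypergeometric probabilities of tables at most as
    likely as the observed one (with a small relative tie tolerance).
    """
    support = np.arange(max(0, col1 - (n - row1)), min(row1, col1) + 1)
    pmf = sps.hypergeom.pmf(support, n, row1, col1)
    ps = np.array([pmf[pmf <= p_obs * (1 + _TIE_RTOL)].sum() for p_obs in pmf])
    return support, np.minimum(ps, 1.0)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Computed by enumerating the hypergeometric distribution with the
    observed margins and summing the probabilities of all tables at most as
    likely as the observed one.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table entries must be non-negative integers")
    n = a + b + c + d
    if n == 0:
        return 1.0
    support, ps = fisher_pvalues_for_margins(n, a + b, a + c)
    return float(ps[int(np.searchsorted(support, a))])


def odds_ratio_haldane(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio ``(a*d)/(b*c)``, with 0.5 added to every cell when
    any cell is zero (Haldane-Anscombe correction)."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float((a * d) / (b * c))


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return sps.false_discovery_control(p, method="bh")


def binomial_count_test(k_treat: int, k_base: int, lib_treat: float, lib_base: float) -> float:
    """Two-sided exact binomial test of a treatment count against the
    proportion expected from relative library sizes.

    Conditional on the total ``k_treat + k_base``, under no difference the
    treatment count is Binomial(n, lib_treat / (lib_treat + lib_base)).
    """
    n = int(k_treat) + int(k_base)
    if n == 0:
        return 1.0
    if lib_treat <= 0 or lib_base <= 0:
        raise ValueError("library sizes must be positive")
    prob = lib_treat / (lib_treat + lib_base)
    return float(sps.binomtest(int(k_treat), n, prob, alternative="two-sided").pvalue)


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the exact t-transform two-sided p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the channels")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
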