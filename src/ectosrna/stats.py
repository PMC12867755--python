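"""Shared statistical kernels.

Pearson chi-square goodness-of-fit and 2x2 association tests (Mendelian
segregation analysis and miRNA-DESL enrichment), Benjamini-Hochberg FDR
adjustment, and rank-sum utilities. Distribution functions come from
scipy; the surface here fixes the conventions used everywhere in the
pipeline (no continuity correction, df = classes - 1, step-up BH).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class GofResult:
    """Goodness-of-fit chi-square result with per-class contributions."""

    chi2: float
    df: int
    p: float
    contributions: Tuple[float, ...]
    critical_value: float
    alpha: float


def chisq_gof(
    observed: Sequence[int],
    expected: Sequence[float],
    alpha: float = 0.05,
) -> GofResult:
    """Pearson chi-square goodness-of-fit test.

    ``observed`` are integer class counts, ``expected`` strictly positive
    expected counts of the same length; df = number of classes - 1. No
    continuity correction is applied.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.ndim != 1 or obs.shape != exp.shape or obs.size < 2:
        raise ValueError("observed and expected must be 1-D, equal length >= 2")
    if np.any(exp <= 0):
        raise ValueError("expected counts must all be positive")
    contributions = (obs - exp) ** 2 / exp
    chi2 = float(contributions.sum())
    df = obs.size - 1
    p = float(sps.chi2.sf(chi2, df))
    return GofResult(
        chi2=chi2,
        df=df,
        p=p,
        contributions=tuple(float(c) for c in contributions),
        critical_value=chi2_quantile(alpha, df),
        alpha=alpha,
    )


def chisq_2x2(a: int, b: int, c: int, d: int) -> Tuple[float, float]:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]], no correction."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("2x2 counts must be non-negative")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (same order as input)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def chi2_quantile(alpha: float, df: int) -> float:
    """Upper-tail chi-square critical value: P(X >= value) = alpha."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(sps.chi2.isf(alpha, df))


def ranksum_exact(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-sided exact rank-sum test by full enumeration of rank splits.

    Computes the Mann-Whitney U for ``x`` and the exact two-sided p-value
    as the fraction of all C(n1+n2, n1) assignments of the pooled
    (midranked) values whose U deviates from n1*n2/2 at least as much as
    the observed one. Ties are handled by midranks entering the
    enumeration, so identical samples give p = 1. Feasible for
    n1 + n2 <= ~20.
    """
    from itertools import combinations

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    center = n1 * n2 / 2
    dev_obs = abs(u_obs - center)
    total = 0
    hits = 0
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - center) >= dev_obs - 1e-12:
            hits += 1
    return float(u_obs), hits / total


def ranksum(x: Sequence[float], y: Sequence[float], exact_max_n: int = 10) -> Tuple[float, float]:
    """Two-sided rank-sum test.

    Exact enumeration when both samples have size <= ``exact_max_n``;
    otherwise the tie-corrected normal approximation
    (scipy ``mannwhitneyu``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size <= exact_max_n and y.size <= exact_max_n:
        return ranksum_exact(x, y)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
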