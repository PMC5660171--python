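"""Nonparametric statistics for side-to-side comparisons.

Mann-Whitney U with midranks for ties, either by full enumeration of the
permutation null (small samples) or by the tie-corrected normal approximation
with continuity correction; Benjamini-Hochberg FDR adjustment; and Pearson
correlation on log-transformed expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: Exact enumeration is used automatically up to this combined sample size.
EXACT_LIMIT = 16


@dataclass(frozen=True)
class TestResult:
    """Two-sided Mann-Whitney result."""

    statistic: float  # U of the first sample
    n1: int
    n2: int
    p_value: float
    method: str  # "exact" or "normal-approx"


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U1 from midranks: R1 - n1(n1+1)/2."""
    n1 = x.size
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    return float(r1 - n1 * (n1 + 1) / 2)


def _exact_p(pooled: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided p by enumerating all C(n1+n2, n1) group labelings.

    Two-sidedness is symmetric around the null mean n1*n2/2: the p-value is
    the fraction of labelings at least as far from the mean as observed.
    """
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mu = n1 * (n - n1) / 2
    d_obs = abs(u_obs - mu) - 1e-9  # tolerance for float rank sums
    hits = 0
    base = n1 * (n1 + 1) / 2
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - base
        if abs(u - mu) >= d_obs:
            hits += 1
    return hits / comb(n, n1)


def _approx_p(pooled: np.ndarray, n1: int, u_obs: float) -> float:
    """Normal approximation with tie-corrected variance and continuity correction."""
    n = pooled.size
    n2 = n - n1
    mu = n1 * n2 / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return 1.0
    z = (abs(u_obs - mu) - 0.5) / sqrt(var)
    z = max(z, 0.0)
    return min(1.0, 2.0 * sps.norm.sf(z))


def mann_whitney_u(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``mode`` is 'exact' (full enumeration), 'approx' (normal approximation),
    or 'auto' (exact when n1 + n2 <= 16).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")
    n1, n2 = x.size, y.size
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    if mode == "auto":
        mode = "exact" if n1 + n2 <= EXACT_LIMIT else "approx"
    if mode == "exact":
        p = _exact_p(pooled, n1, u)
        method = "exact"
    else:
        p = _approx_p(pooled, n1, u)
        method = "normal-approx"
    return TestResult(statistic=u, n1=n1, n2=n2, p_value=max(p, np.finfo(float).tiny),
                      method=method)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def pearson_log(x, y, pseudocount: float = 1.0) -> float:
    """Pearson r of log(value + pseudocount) expression vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("expression values must be non-negative")
    lx, ly = np.log(x + pseudocount), np.log(y + pseudocount)
    if np.allclose(lx, lx[0]) or np.allclose(ly, ly[0]):
        raise ValueError("undefined correlation: zero variance after log transform")
    return float(sps.pearsonr(lx, ly).statistic)
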