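"""Exact small-sample tests: Fisher 2x2, Hardy-Weinberg, Wilcoxon.

These tests back the homogeneity/HKA gene scans, the HWE genotype filter
and the sex-scaffold coverage comparisons.  Each test enumerates its full
conditional null distribution for small samples; the Wilcoxon tests fall
back to a normal approximation (with continuity and tie corrections) for
larger samples or when ties make the permutation distribution non-standard.

Two-sided p-values follow the "sum of outcomes no more probable than the
observed one" convention, with a small relative tolerance when comparing
probabilities so that floating-point noise does not split exact ties.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy.stats import norm

_TIE_REL_TOL = 1e-7

# log-factorial table, grown on demand
_LOGFACT = np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, 2049)))])


def _logfact(n: int) -> float:
    global _LOGFACT
    if n >= _LOGFACT.size:
        m = max(2 * _LOGFACT.size, n + 1)
        _LOGFACT = np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, m)))])
    return float(_LOGFACT[n])


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact test for the table [[a, b], [c, d]].

    Returns the sum of hypergeometric probabilities of all tables with the
    same margins whose probability does not exceed the observed table's
    (relative tolerance 1e-7 for ties).  Any zero margin gives p = 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if 0 in (r1, r2, c1, c2):
        return 1.0
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    global _LOGFACT
    _logfact(n)  # ensure table coverage
    lf = _LOGFACT
    # log P(a = k | margins)
    const = lf[r1] + lf[r2] + lf[c1] + lf[c2] - lf[n]
    logp = const - (lf[ks] + lf[r1 - ks] + lf[c1 - ks] + lf[r2 - c1 + ks])
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[a - lo]
    return float(min(1.0, p[p <= p_obs * (1.0 + _TIE_REL_TOL)].sum()))


def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test on diploid genotype counts.

    Conditions on the observed allele counts and enumerates every
    heterozygote count with matching margins; p is the summed probability
    of configurations no more probable than the observed one.  Monomorphic
    or empty samples return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        return 1.0
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_A, n_a)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    _logfact(2 * n)
    lf = _LOGFACT
    homs_rare = (rare - hets) // 2
    homs_common = (max(n_A, n_a) - hets) // 2
    logp = (
        lf[n]
        - lf[hets]
        - lf[homs_rare]
        - lf[homs_common]
        + hets * math.log(2.0)
        + lf[n_A]
        + lf[n_a]
        - lf[2 * n]
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[np.nonzero(hets == n_Aa)[0][0]]
    return float(min(1.0, p[p <= p_obs * (1.0 + _TIE_REL_TOL)].sum()))


# ---------------------------------------------------------------------------
# Wilcoxon tests


@lru_cache(maxsize=256)
def _ranksum_null(n: int, m: int) -> np.ndarray:
    """P(rank-sum of the size-n group = w) for w = 0..n*(n+m+...).

    Index w is the sum of the n ranks drawn without replacement from
    1..n+m.  Computed by the classic subset-sum dynamic programme.
    """
    N = n + m
    max_sum = n * (2 * N - n + 1) // 2
    # ways[k][s] = number of k-subsets of {1..N} with sum s
    ways = np.zeros((n + 1, max_sum + 1))
    ways[0, 0] = 1.0
    for r in range(1, N + 1):
        for k in range(min(r, n), 0, -1):
            ways[k, r:] += ways[k - 1, :-r] if r else ways[k - 1, :]
    total = math.comb(N, n)
    return ways[n] / total


@lru_cache(maxsize=256)
def _signedrank_null(n: int) -> np.ndarray:
    """P(W+ = w) for the signed-rank statistic with n untied ranks."""
    max_sum = n * (n + 1) // 2
    ways = np.zeros(max_sum + 1)
    ways[0] = 1.0
    for r in range(1, n + 1):
        ways[r:] = ways[r:] + ways[:-r]
    return ways / (2.0**n)


def _tail_p(dist: np.ndarray, w: int, alternative: str, midp: bool = False) -> float:
    less = float(dist[: w + 1].sum())
    greater = float(dist[w:].sum())
    if midp:
        half = 0.5 * float(dist[w])
        less -= half
        greater -= half
    if alternative == "less":
        p = less
    elif alternative == "greater":
        p = greater
    elif alternative == "two-sided":
        p = 2.0 * min(less, greater)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(min(1.0, max(p, 0.0)))


def wilcoxon_rank_sum_exact(
    x, y, alternative: str = "two-sided", exact_limit: int = 12
) -> float:
    """Wilcoxon rank-sum (Mann-Whitney) test of two independent samples.

    ``alternative='less'`` tests that x tends to be smaller than y.  The
    exact permutation distribution is enumerated when the combined sample
    size is at most ``exact_limit`` and there are no ties; otherwise a
    normal approximation with continuity and tie corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n, m = x.size, y.size
    combined = np.concatenate([x, y])
    order = np.argsort(combined, kind="mergesort")
    ranks = np.empty(combined.size)
    sorted_vals = combined[order]
    # mid-ranks
    i = 0
    base = np.arange(1.0, combined.size + 1)
    while i < combined.size:
        j = i
        while j + 1 < combined.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = base[i : j + 1].mean()
        i = j + 1
    w = float(ranks[:n].sum())
    has_ties = np.unique(combined).size < combined.size
    if n + m <= exact_limit and not has_ties:
        dist = _ranksum_null(n, m)
        return _tail_p(dist, int(round(w)), alternative)
    # normal approximation
    N = n + m
    mu = n * (N + 1) / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (N * (N - 1)) if N > 1 else 0.0
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return 1.0
    sd = math.sqrt(var)
    if alternative == "less":
        return float(norm.cdf((w - mu + 0.5) / sd))
    if alternative == "greater":
        return float(norm.sf((w - mu - 0.5) / sd))
    if alternative == "two-sided":
        z = (abs(w - mu) - 0.5) / sd
        return float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))
    raise ValueError(f"unknown alternative {alternative!r}")


def wilcoxon_signed_rank_exact(
    x,
    mu0: float = 0.0,
    alternative: str = "two-sided",
    exact_limit: int = 20,
    midp: bool = False,
) -> float:
    """One-sample Wilcoxon signed-rank test of location against ``mu0``.

    Zero differences are dropped.  ``alternative='less'`` tests that x is
    located below mu0 (small W+).  Exact sign enumeration is used for at
    most ``exact_limit`` non-zero untied differences, otherwise a normal
    approximation with continuity and tie corrections.  ``midp=True``
    applies the mid-p convention (half weight on the observed statistic),
    which reduces the conservatism of the discrete exact test at very
    small n.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("sample must be non-empty")
    d = x - mu0
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    absd = np.abs(d)
    order = np.argsort(absd, kind="mergesort")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    base = np.arange(1.0, n + 1)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i : j + 1]] = base[i : j + 1].mean()
        i = j + 1
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(absd).size < n
    if n <= exact_limit and not has_ties:
        dist = _signedrank_null(n)
        return _tail_p(dist, int(round(w_plus)), alternative, midp=midp)
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(absd, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float((counts**3 - counts).sum()) / 48.0
    if var <= 0:
        return 1.0
    sd = math.sqrt(var)
    if alternative == "less":
        return float(norm.cdf((w_plus - mu + 0.5) / sd))
    if alternative == "greater":
        return float(norm.sf((w_plus - mu - 0.5) / sd))
    if alternative == "two-sided":
        z = (abs(w_plus - mu) - 0.5) / sd
        return float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))
    raise ValueError(f"unknown alternative {alternative!r}")
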