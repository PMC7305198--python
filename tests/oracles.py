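"""Brute-force allele-level oracles for the diversity statistics.

Independent of the package implementation: enumerate alleles and pairs
explicitly, use textbook formulas term by term.
"""

import itertools

import numpy as np




def alleles_of(matrix, idx, site):
    out = []
    for j in idx:
        g = matrix.genotypes[site, j]
        if g >= 0:
            out.extend([1] * g + [0] * (2 - g))
    return out


def pi_oracle(matrix, idx, rows, length):
    total = 0.0
    for s in rows:
        al = alleles_of(matrix, idx, s)
        n = len(al)
        if n < 2:
            continue
        diffs = sum(a != b for a, b in itertools.combinations(al, 2))
        total += diffs / (n * (n - 1) / 2)
    return total / length


def dxy_oracle(matrix, ia, ib, rows, length):
    total = 0.0
    for s in rows:
        aa = alleles_of(matrix, ia, s)
        bb = alleles_of(matrix, ib, s)
        if not aa or not bb:
            continue
        diffs = sum(x != y for x in aa for y in bb)
        total += diffs / (len(aa) * len(bb))
    return total / length


def theta_oracle(matrix, idx, rows, n_alleles, length):
    s = 0
    for r in rows:
        al = alleles_of(matrix, idx, r)
        if al and 0 < sum(al) < len(al):
            s += 1
    a = sum(1.0 / i for i in range(1, n_alleles))
    return s / a / length


def tajima_oracle(matrix, idx, rows, n):
    s = 0
    pi_total = 0.0
    for r in rows:
        al = alleles_of(matrix, idx, r)
        if not al:
            continue
        k = len(al)
        if k >= 2 and 0 < sum(al) < k:
            s += 1
        if k >= 2:
            diffs = sum(a != b for a, b in itertools.combinations(al, 2))
            pi_total += diffs / (k * (k - 1) / 2)
    if s == 0:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_total - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))


def fst_oracle(matrix, ia, ib, rows):
    """Textbook Weir-Cockerham (1984) two-population estimator, ratio of sums."""
    num = den = 0.0
    r = 2
    for s in rows:
        stats = []
        for idx in (ia, ib):
            gts = [matrix.genotypes[s, j] for j in idx if matrix.genotypes[s, j] >= 0]
            if not gts:
                stats = None
                break
            ni = len(gts)
            pi = sum(gts) / (2 * ni)
            hi = sum(g == 1 for g in gts) / ni
            stats.append((ni, pi, hi))
        if stats is None or stats[0][0] + stats[1][0] <= 2:
            continue
        (n1, p1, h1), (n2, p2, h2) = stats
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = nbar / nc * (
            s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
        )
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    if den == 0:
        return float("nan")
    return min(max(num / den, 0.0), 1 - 1e-9)


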