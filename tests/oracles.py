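"""Independent brute-force oracles used by the test suite.

Each routine recomputes a statistic by direct enumeration or elementary
arithmetic, sharing no code path with the package implementation.
"""

from itertools import combinations
from math import comb

import numpy as np


def exact_ranksum_p(x, y, alternative="two-sided"):
    """Wilcoxon rank-sum p by enumerating all C(n, nx) group assignments.

    Uses the rank-sum of x as the test statistic (values must be tie-free
    for the enumeration to match the continuous-case null exactly).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1.0
    nx = len(x)
    w_obs = ranks[:nx].sum()
    total = comb(len(pooled), nx)
    ge = gt = le = 0
    for idx in combinations(range(len(pooled)), nx):
        w = ranks[list(idx)].sum()
        if w >= w_obs - 1e-9:
            ge += 1
        if w <= w_obs + 1e-9:
            le += 1
    p_greater = ge / total
    p_less = le / total
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2 * min(p_greater, p_less))


def fisher_two_sided_p(a, b, c, d):
    """Two-sided Fisher p by summing hypergeometric point masses <= observed."""
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    denom = comb(n, c1)

    def pmf(k):
        if k < max(0, c1 - (n - r1)) or k > min(r1, c1):
            return 0.0
        return comb(r1, k) * comb(n - r1, c1 - k) / denom

    p_obs = pmf(a)
    return min(1.0, sum(pk for k in range(0, min(r1, c1) + 1)
                        if (pk := pmf(k)) <= p_obs * (1 + 1e-9)))


def hypergeom_upper_p(overlap, universe, term, query):
    """P(X >= overlap) for X ~ Hypergeom(universe, term, query)."""
    denom = comb(universe, query)
    return sum(
        comb(term, k) * comb(universe - term, query - k) / denom
        for k in range(overlap, min(term, query) + 1)
    )


def stemness_by_hand(counts, totals, scale, up_cols, down_cols):
    """Direct per-cell stemness recomputation on a dense count array."""
    counts = np.asarray(counts, float)
    scores = []
    for i in range(counts.shape[0]):
        def identity(cols):
            n = sum(counts[i, j] > 0 for j in cols)
            s = sum(np.log1p(counts[i, j] / totals[i] * scale) for j in cols)
            return n + s
        stem = identity(up_cols)
        fib = identity(down_cols)
        scores.append((stem + 1) / (fib + 1))
    return np.array(scores)


def pooled_t(x, y):
    """Equal-variance two-sample t statistic by the closed-form formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    return (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
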