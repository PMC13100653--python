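"""Independent brute-force oracles used to freeze expected values.

Each oracle is deliberately naive — enumeration or direct counting — and
shares no code with the implementation paths it checks.
"""

from __future__ import annotations

import math
from itertools import combinations, product

import numpy as np


def dtw_bruteforce(a, b) -> float:
    """Minimal accumulated |a_i - b_j| over all monotone warping paths.

    Enumerates every path from (0, 0) to (n-1, m-1) with steps right/down/
    diagonal by depth-first search; exponential, so keep series short.
    """
    a, b = list(a), list(b)
    n, m = len(a), len(b)
    best = [math.inf]

    def walk(i, j, cost):
        cost += abs(a[i] - b[j])
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ni, nj = i + di, j + dj
            if ni < n and nj < m:
                walk(ni, nj, cost)

    walk(0, 0, 0.0)
    return best[0]


def kmedoids_bruteforce(D: np.ndarray, k: int) -> float:
    """Optimal k-medoids cost by exhaustive search over medoid subsets."""
    n = D.shape[0]
    return min(
        float(D[:, list(meds)].min(axis=1).sum()) for meds in combinations(range(n), k)
    )


def auc_paircount(scores, labels) -> float:
    """AUC as the concordance probability over positive-negative pairs."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos = s[y == 1]
    neg = s[y == 0]
    num = 0.0
    for p in pos:
        for q in neg:
            num += 1.0 if p > q else (0.5 if p == q else 0.0)
    return num / (len(pos) * len(neg))


def youden_bruteforce(values_high, values_low):
    """Best (cutoff, J) over midpoints of adjacent distinct pooled values."""
    hi = np.asarray(values_high, float)
    lo = np.asarray(values_low, float)
    pooled = np.unique(np.concatenate([hi, lo]))
    best = (float(pooled[0]), 0.0)
    if pooled.size < 2:
        return best
    first = True
    for c in 0.5 * (pooled[:-1] + pooled[1:]):
        J = (hi < c).mean() + (lo >= c).mean() - 1.0
        if first or J > best[1] + 1e-12:
            best = (float(c), float(J))
            first = False
    if best[1] < 0.0:  # inverted groups: the no-positive boundary wins
        return (float(pooled[0]), 0.0)
    return best


def fisher_hypergeom(table) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    p_obs = pmf(a)
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = pmf(k)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)
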