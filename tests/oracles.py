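"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import math

import numpy as np


def naive_derivatives(S, C, net):
    """Double-loop evaluation of the mediator/growth equations.

    Deliberately scalar and index-by-index, independent of the vectorised
    implementation it checks.
    """
    n_s = len(S)
    n_m = len(C)
    dC = [0.0] * n_m
    for i in range(n_m):
        for j in range(n_s):
            uptake = net.consumption_rate[i][j] * C[i] / (C[i] + net.saturation[j][i])
            dC[i] += (net.production_rate[i][j] - uptake) * S[j]
    dS = [0.0] * n_s
    for i in range(n_s):
        rate = net.basal_rate[i]
        for j in range(n_m):
            rate += net.influence_rate[i][j] * C[j] / (C[j] + net.saturation[i][j])
        dS[i] = rate * S[i]
    return np.array(dS), np.array(dC)


def binom_sf_at_least(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), by exact tail summation."""
    if k <= 0:
        return 1.0
    if p <= 0.0:
        return 0.0
    if p >= 1.0:
        return 1.0
    return sum(math.comb(n, j) * p**j * (1.0 - p) ** (n - j) for j in range(k, n + 1))


def binom_cdf_at_most(k: int, n: int, p: float) -> float:
    """P(X <= k) for X ~ Binomial(n, p), by exact tail summation."""
    if k >= n:
        return 1.0
    if p <= 0.0:
        return 1.0
    if p >= 1.0:
        return 0.0
    return sum(math.comb(n, j) * p**j * (1.0 - p) ** (n - j) for j in range(0, k + 1))


def clopper_pearson_bruteforce(k: int, n: int, level: float, tol: float = 1e-10):
    """Exact binomial CI endpoints by bisecting the binomial tail sums.

    The lower endpoint solves P(X >= k | p) = (1-level)/2 and the upper
    endpoint solves P(X <= k | p) = (1-level)/2, with the conventional
    closures at k = 0 and k = n.
    """
    a = (1.0 - level) / 2.0

    def bisect(f, target):
        lo, hi = 0.0, 1.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if f(mid) < target:
                hi = mid
            else:
                lo = mid
            if hi - lo < tol:
                break
        return 0.5 * (lo + hi)

    low = 0.0 if k == 0 else bisect(lambda p: 1.0 - binom_sf_at_least(k, n, p), 1.0 - a)
    high = 1.0 if k == n else bisect(lambda p: binom_cdf_at_most(k, n, p), a)
    return low, high
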