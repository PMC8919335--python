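"""Independent statistical oracles used only by the test suite.

These are deliberately naive and route through none of the package's (or
scipy.stats') closed-form code paths: the t CDF is numerically
integrated from the density, and Fisher/hypergeometric probabilities are
exact rational enumerations over integer tables.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
from scipy.integrate import quad


def t_two_tailed_p(t: float, df: float) -> float:
    """Two-tailed Student-t p by numerical integration of the density."""
    if not math.isfinite(t):
        return 0.0
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))

    def density(x):
        return c * (1 + x * x / df) ** (-(df + 1) / 2)

    tail, _ = quad(density, abs(t), math.inf, epsabs=1e-13, epsrel=1e-13)
    return min(2.0 * tail, 1.0)


def welch_by_hand(a, b):
    """Welch t, df from the textbook formulas (no shared code with ra.py's
    vectorised path beyond arithmetic)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df


def hypergeom_pmf(k: int, N: int, K: int, n: int) -> Fraction:
    if k < max(0, n + K - N) or k > min(K, n):
        return Fraction(0)
    return Fraction(math.comb(K, k) * math.comb(N - K, n - k), math.comb(N, n))


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by direct summation of exact rational terms."""
    total = sum(hypergeom_pmf(j, N, K, n) for j in range(k, min(K, n) + 1))
    return float(total)


def fisher_two_sided(table) -> float:
    """Two-sided Fisher p by exhaustive enumeration at fixed margins.

    Sums P(table') over all tables with the observed margins whose
    probability does not exceed the observed table's (with the standard
    1e-7 relative guard against floating ties).
    """
    (a, b), (c, d) = table
    r1, c1, N = a + b, a + c, a + b + c + d
    p_obs = hypergeom_pmf(a, N, c1, r1)
    gate = p_obs + p_obs * Fraction(1, 10**7)
    total = Fraction(0)
    for x in range(max(0, r1 + c1 - N), min(r1, c1) + 1):
        p = hypergeom_pmf(x, N, c1, r1)
        if p <= gate:
            total += p
    return float(min(total, Fraction(1)))


def exhaustive_permutation_p(a, b):
    """Exact two-sided permutation p-value for the mean difference over
    all assignments of the pooled values into groups of the observed
    sizes."""
    pooled = list(a) + list(b)
    n = len(a)
    obs = abs(np.mean(a) - np.mean(b))
    idx = range(len(pooled))
    hits = 0
    total = 0
    arr = np.asarray(pooled, float)
    for comb in combinations(idx, n):
        sel = np.zeros(len(pooled), bool)
        sel[list(comb)] = True
        diff = abs(arr[sel].mean() - arr[~sel].mean())
        hits += diff >= obs - 1e-12
        total += 1
    return hits / total
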