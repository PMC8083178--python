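"""Independent brute-force oracles used to freeze expected values.

Everything here is written from the textbook definitions (factorials,
explicit pmf sums, literal step-up formula) and never calls the package
under test.
"""

from math import comb, exp, factorial, lgamma

import numpy as np


def hypergeom_tail(k: int, T: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(T, K, n) by binomial-coefficient sums."""
    denom = comb(T, n)
    total = 0
    for x in range(k, min(K, n) + 1):
        if n - x > T - K:
            continue
        total += comb(K, x) * comb(T - K, n - x)
    return total / denom


def poisson_tail(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam) via 1 - partial pmf sum."""
    if k <= 0:
        return 1.0
    return 1.0 - sum(exp(-lam) * lam ** x / factorial(x) for x in range(k))


def nbinom_tail(k: int, r: float, p: float) -> float:
    """P(X >= k) for NB(r, p) counting failures; pmf from the gamma form."""
    if k <= 0:
        return 1.0
    def pmf(x: int) -> float:
        return exp(lgamma(x + r) - lgamma(r) - lgamma(x + 1)
                   + r * np.log(p) + x * np.log(1 - p))
    return 1.0 - sum(pmf(x) for x in range(k))


def binomial_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p) by explicit pmf summation."""
    if k <= 0:
        return 1.0
    return sum(comb(n, x) * p ** x * (1 - p) ** (n - x) for x in range(k, n + 1))


def bh_stepup(pvalues):
    """Literal Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        q[i] = min(1.0, running_min)
    return q


def weibull_sf_numeric(x: float, k: float, lam: float, n_grid: int = 2_000_000) -> float:
    """Weibull survival by trapezoidal integration of the density on [x, hi]."""
    hi = lam * (-np.log(1e-18)) ** (1 / k)
    t = np.linspace(x, max(hi, x * 2), n_grid)
    dens = (k / lam) * (t / lam) ** (k - 1) * np.exp(-((t / lam) ** k))
    return float(np.trapezoid(dens, t))
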