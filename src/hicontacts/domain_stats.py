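"""Domain-mode statistics: aggregate the bin map into a domain-pair count
matrix and score pairs under hypergeometric, Poisson or negative-binomial
nulls.

Null parameterization: with K_i the marginal contact count of domain i and
T the grand total of unordered domain-pair counts, the expected count of
pair (i, j) is mu_ij = K_i * K_j / (2 T).  The hypergeometric test draws
K_j contacts from a population of T with K_i successes.  All tests are
one-sided for enrichment, P(X >= k).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .hic_io import Domain, HiCMap
from .region_stats import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "DomainMatrix",
    "DomainCall",
    "DomainCallSet",
    "TESTS",
    "aggregate",
    "hypergeom_pvalue",
    "poisson_pvalue",
    "nbinom_pvalue",
    "fit_dispersion",
    "call_domain_interactions",
]

TESTS = ("hypergeometric", "poisson", "nbinom")
DEFAULT_ALPHA = 0.01


@dataclass
class DomainMatrix:
    """N x N aggregated domain-pair contact counts with marginals.

    ``raw`` keeps the exact aggregated sums; ``M`` is ``raw`` rounded to the
    nearest integer for the discrete count tests.  ``K[i] = sum_j M[i, j]``
    and ``T = sum_{i <= j} M[i, j]``.
    """

    domains: list[Domain]
    raw: np.ndarray
    M: np.ndarray = field(init=False)
    K: np.ndarray = field(init=False)
    T: int = field(init=False)

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw, dtype=float)
        if not np.allclose(raw, raw.T):
            raise ValueError("aggregated matrix must be symmetric")
        if not np.allclose(raw, np.rint(raw)):
            logger.warning("non-integer aggregated counts; rounding for count tests")
        self.raw = raw
        self.M = np.rint(raw).astype(np.int64)
        self.K = self.M.sum(axis=1)
        self.T = int((self.M.sum() + np.trace(self.M)) // 2)

    @property
    def n_domains(self) -> int:
        return self.M.shape[0]


def aggregate(hic: HiCMap, domains: list[Domain]) -> DomainMatrix:
    """Sum the bin-level map into a domain-pair contact matrix.

    ``M[i, j]`` is the sum of map entries over all (bin in i, bin in j)
    cells; bins not covered by any domain contribute nowhere.
    """
    if not domains:
        raise ValueError("empty domain list")
    n = hic.n_bins
    for d in domains:
        if d.bin_start < 0 or d.bin_end >= n:
            raise ValueError(
                f"domain [{d.start},{d.end}) bins [{d.bin_start},{d.bin_end}] "
                f"outside map with {n} bins"
            )
    # row-sum then column-sum via slicing; domains are contiguous bin ranges
    nd = len(domains)
    raw = np.empty((nd, nd))
    row_agg = np.array([
        hic.matrix[d.bin_start: d.bin_end + 1].sum(axis=0) for d in domains
    ])
    for j, d in enumerate(domains):
        raw[:, j] = row_agg[:, d.bin_start: d.bin_end + 1].sum(axis=1)
    raw = (raw + raw.T) / 2.0   # exact in theory; guards float noise
    return DomainMatrix(domains=list(domains), raw=raw)


def _check_pair(dm: DomainMatrix, i: int, j: int) -> None:
    if not 0 <= i < j < dm.n_domains:
        raise ValueError(f"need 0 <= i < j < {dm.n_domains}, got ({i}, {j})")


def hypergeom_pvalue(dm: DomainMatrix, i: int, j: int) -> float:
    """P(X >= M[i,j]) for X ~ Hypergeom(population T, successes K_i, draws K_j)."""
    _check_pair(dm, i, j)
    T, Ki, Kj, k = dm.T, int(dm.K[i]), int(dm.K[j]), int(dm.M[i, j])
    if Ki + Kj > T:
        logger.warning("pair (%d,%d): K_i + K_j = %d > T = %d; clipping", i, j, Ki + Kj, T)
        Ki, Kj = min(Ki, T), min(Kj, T)
    if k > min(Ki, Kj):
        raise ValueError(f"count {k} exceeds min(K_i, K_j) = {min(Ki, Kj)}")
    return float(stats.hypergeom.sf(k - 1, T, Ki, Kj))


def _pair_mean(dm: DomainMatrix, i: int, j: int) -> float:
    return float(dm.K[i]) * float(dm.K[j]) / (2.0 * dm.T)


def poisson_pvalue(dm: DomainMatrix, i: int, j: int) -> float:
    """P(X >= M[i,j]) for X ~ Poisson(K_i K_j / 2T)."""
    _check_pair(dm, i, j)
    lam = _pair_mean(dm, i, j)
    k = int(dm.M[i, j])
    if lam == 0:
        if k > 0:
            logger.warning("pair (%d,%d): zero expectation with count %d", i, j, k)
            return 0.0
        return 1.0
    return float(stats.poisson.sf(k - 1, lam))


def nbinom_pvalue(dm: DomainMatrix, i: int, j: int, dispersion: float) -> float:
    """P(X >= M[i,j]) under NB with mean mu and variance mu + dispersion*mu^2.

    Dispersion <= 0 degenerates to the Poisson test.
    """
    _check_pair(dm, i, j)
    if dispersion <= 0:
        return poisson_pvalue(dm, i, j)
    mu = _pair_mean(dm, i, j)
    k = int(dm.M[i, j])
    if mu == 0:
        return 0.0 if k > 0 else 1.0
    r = 1.0 / dispersion
    p_nb = r / (r + mu)
    return float(stats.nbinom.sf(k - 1, r, p_nb))


def fit_dispersion(dm: DomainMatrix, min_pairs: int = 10, robust: bool = False) -> float:
    """Method-of-moments dispersion over all i < j pairs.

    phi = max(0, sum[(k_ij - mu_ij)^2 - mu_ij] / sum mu_ij^2).

    With ``robust=True`` iterative refit passes drop pairs that are
    outliers under the current fit (two-sided NB tail below 1 / n_pairs),
    so a few strongly enriched pairs cannot inflate the null dispersion and
    mask themselves.
    """
    n = dm.n_domains
    iu = np.triu_indices(n, k=1)
    if iu[0].size < min_pairs:
        raise ValueError(
            f"only {iu[0].size} off-diagonal pairs (< {min_pairs}); use the Poisson test"
        )
    k = dm.M[iu].astype(float)
    mu = np.array([_pair_mean(dm, int(a), int(b)) for a, b in zip(*iu)])

    def mom(kk: np.ndarray, mm: np.ndarray) -> float:
        denom = (mm ** 2).sum()
        if denom == 0:
            return 0.0
        return float(max(0.0, ((kk - mm) ** 2 - mm).sum() / denom))

    phi_all = mom(k, mu)
    if not robust:
        return phi_all

    # start from a median-based estimate so contaminated pairs cannot hide
    # inside an inflated initial dispersion; fall back to the plain estimate
    # if the exclusion would throw away most of the data
    cutoff = 1.0 / k.size
    min_kept = max(min_pairs, k.size // 2)
    pos = mu > 0
    if not pos.any():
        return phi_all
    s = ((k[pos] - mu[pos]) ** 2 - mu[pos]) / mu[pos] ** 2
    phi = max(0.0, float(np.median(s)) / 0.455)   # median chi2_1 = 0.455
    keep = np.ones(k.size, dtype=bool)
    for _ in range(10):
        if phi > 0:
            r = 1.0 / phi
            p_nb = r / (r + mu)
            upper = stats.nbinom.sf(k - 1, r, p_nb)
            lower = stats.nbinom.cdf(k, r, p_nb)
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                upper = stats.poisson.sf(k - 1, mu)
                lower = stats.poisson.cdf(k, mu)
        new_keep = (np.minimum(upper, lower) >= cutoff) | (mu == 0)
        if new_keep.sum() < min_kept:
            logger.info("dispersion outlier screen rejected >half the pairs; "
                        "using the plain estimate %.4g", phi_all)
            return phi_all
        if (new_keep == keep).all() and phi > 0:
            break
        keep = new_keep
        phi = mom(k[keep], mu[keep])
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dispersion fit excluded %d outlier pairs", n_dropped)
    return phi


@dataclass
class DomainCall:
    i: int
    j: int
    test: str
    p: float
    q: float


@dataclass
class DomainCallSet:
    """Significant domain pairs plus the full p/q matrices."""

    chromosome: str
    test: str
    alpha: float
    domains: list[Domain]
    calls: list[DomainCall]
    p_matrix: np.ndarray
    q_matrix: np.ndarray

    def __len__(self) -> int:
        return len(self.calls)


def call_domain_interactions(
    hic: HiCMap,
    domains: list[Domain],
    test: str = "hypergeometric",
    alpha: float = DEFAULT_ALPHA,
    min_separation: int = 0,
) -> DomainCallSet:
    """Aggregate, score every i < j domain pair, BH-correct, threshold.

    ``min_separation`` excludes pairs with |i - j| <= min_separation (0 tests
    adjacent domains too).  The intra-domain diagonal is never tested.
    """
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}; choose from {TESTS}")
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    dm = aggregate(hic, domains)
    n = dm.n_domains
    phi = fit_dispersion(dm, robust=True) if test == "nbinom" else 0.0

    p_matrix = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            if j - i <= min_separation:
                continue
            if test == "hypergeometric":
                p_matrix[i, j] = hypergeom_pvalue(dm, i, j)
            elif test == "poisson":
                p_matrix[i, j] = poisson_pvalue(dm, i, j)
            else:
                p_matrix[i, j] = nbinom_pvalue(dm, i, j, phi)
            p_matrix[j, i] = p_matrix[i, j]

    iu = np.triu_indices(n, k=1)
    q_upper = bh_fdr(p_matrix[iu])
    q_matrix = np.full((n, n), np.nan)
    q_matrix[iu] = q_upper
    q_matrix[iu[1], iu[0]] = q_upper

    calls = [
        DomainCall(int(i), int(j), test, float(p_matrix[i, j]), float(q_matrix[i, j]))
        for i, j in zip(*iu)
        if not np.isnan(q_matrix[i, j]) and q_matrix[i, j] <= alpha
    ]
    return DomainCallSet(
        chromosome=hic.chromosome, test=test, alpha=alpha, domains=list(domains),
        calls=calls, p_matrix=p_matrix, q_matrix=q_matrix,
    )


def write_value_matrix(
    callset: DomainCallSet, values: np.ndarray, path,
) -> None:
    """Write per-pair values as rows: chrom, i_start, i_end, j_start, j_end, value."""
    lines = ["#chrom\tdomain_i_start\tdomain_i_end\tdomain_j_start\tdomain_j_end\tvalue"]
    doms = callset.domains
    n = len(doms)
    for i in range(n):
        for j in range(i + 1, n):
            v = values[i, j]
            if np.isnan(v):
                continue
            lines.append(
                f"{callset.chromosome}\t{doms[i].start}\t{doms[i].end}\t"
                f"{doms[j].start}\t{doms[j].end}\t{v:.6e}"
            )
    from pathlib import Path
    Path(path).write_text("\n".join(lines) + "\n")
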