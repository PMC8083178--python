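"""Compartment analysis: PC1 of the observed/expected correlation map,
majority-vote domain classification, and same-compartment preference tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .domain_stats import DomainCallSet
from .hic_io import Domain, HiCMap

logger = logging.getLogger(__name__)

__all__ = [
    "CompartmentAssignment",
    "EnrichmentReport",
    "pc1",
    "classify_domains",
    "compartment_enrichment",
]

MIN_NONEMPTY_BINS = 10


def pc1(hic: HiCMap) -> np.ndarray:
    """Per-bin first-principal-component scores of the contact map.

    Pipeline: divide each entry by the mean of its diagonal
    (observed/expected), take the Pearson correlation matrix of the result,
    then the first principal component of that correlation matrix.  Empty
    bins (all-zero rows) get NaN.  The sign is oriented so that PC1
    correlates positively with bin coverage; ties are left as-is.
    """
    m = hic.matrix
    n = hic.n_bins
    nonempty = m.sum(axis=1) > 0
    if nonempty.sum() < MIN_NONEMPTY_BINS:
        raise ValueError(f"need >= {MIN_NONEMPTY_BINS} non-empty bins, got {int(nonempty.sum())}")
    sub = m[np.ix_(nonempty, nonempty)]
    k = sub.shape[0]

    # observed / expected: divide each diagonal by its mean
    oe = np.zeros_like(sub)
    for d in range(k):
        idx = (np.arange(k - d), np.arange(d, k))
        mean_d = sub[idx].mean()
        if mean_d > 0:
            oe[idx] = sub[idx] / mean_d
            if d > 0:
                oe[idx[1], idx[0]] = oe[idx]

    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(oe)
    if np.isnan(corr).all():
        raise ValueError("degenerate map: correlation matrix undefined")
    corr = np.nan_to_num(corr, nan=0.0)
    if np.allclose(corr, corr[0, 0]):
        raise ValueError("degenerate map: constant correlation matrix")

    centered = corr - corr.mean(axis=0, keepdims=True)
    cov = centered.T @ centered
    eigvals, eigvecs = np.linalg.eigh(cov)
    lead = eigvecs[:, -1]
    scores = centered @ lead

    coverage = sub.sum(axis=1)
    orient = np.corrcoef(scores, coverage)[0, 1]
    if np.isfinite(orient) and orient < 0:
        scores = -scores

    out = np.full(n, np.nan)
    out[nonempty] = scores
    return out


@dataclass
class CompartmentAssignment:
    """Per-bin PC1 values and per-domain sign labels.

    ``labels[k]`` is +1 (positive), -1 (negative) or 0 (unclassified, all
    bins missing).  ``tie_flags[k]`` marks domains whose bin-sign vote was
    tied and broken by the sign of the summed PC1.
    """

    pc1_values: np.ndarray
    domains: list[Domain]
    labels: np.ndarray
    n_positive_bins: np.ndarray
    n_negative_bins: np.ndarray
    tie_flags: np.ndarray

    def counts(self) -> tuple[int, int]:
        """(number of positive domains, number of negative domains)."""
        return int((self.labels == 1).sum()), int((self.labels == -1).sum())


def classify_domains(pc1_values: np.ndarray, domains: list[Domain]) -> CompartmentAssignment:
    """Majority-vote sign classification of domains from per-bin PC1.

    Missing-PC1 bins abstain; a tie is broken to the sign of the summed PC1
    over the domain's bins (flagged).  Domains with no informative bins are
    unclassified (label 0).
    """
    nd = len(domains)
    labels = np.zeros(nd, dtype=int)
    n_pos = np.zeros(nd, dtype=int)
    n_neg = np.zeros(nd, dtype=int)
    ties = np.zeros(nd, dtype=bool)
    for k, d in enumerate(domains):
        vals = pc1_values[d.bin_start: d.bin_end + 1]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            logger.warning("domain [%d,%d): all bins missing PC1; unclassified", d.start, d.end)
            continue
        n_pos[k] = int((vals > 0).sum())
        n_neg[k] = int((vals < 0).sum())
        if n_pos[k] > n_neg[k]:
            labels[k] = 1
        elif n_neg[k] > n_pos[k]:
            labels[k] = -1
        else:
            labels[k] = 1 if vals.sum() >= 0 else -1
            ties[k] = True
            logger.info("domain [%d,%d): tied sign vote, broken by PC1 sum", d.start, d.end)
    return CompartmentAssignment(
        pc1_values=pc1_values, domains=list(domains), labels=labels,
        n_positive_bins=n_pos, n_negative_bins=n_neg, tie_flags=ties,
    )


@dataclass
class EnrichmentReport:
    """Compartment-pair composition of significant domain calls."""

    observed: dict[str, int]          # keys "++", "--", "+-"
    expected_proportions: dict[str, float]
    expected_counts: dict[str, float]
    chi2_statistic: float
    chi2_pvalue: float
    binomial_depletion_pvalue: float  # one-sided, fewer +- pairs than expected
    n_pairs: int
    n_positive_domains: int
    n_negative_domains: int

    def as_text(self) -> str:
        lines = ["category\tobserved\texpected"]
        for key in ("++", "--", "+-"):
            lines.append(f"{key}\t{self.observed[key]}\t{self.expected_counts[key]:.3f}")
        lines.append(f"chi2_statistic\t{self.chi2_statistic:.6g}")
        lines.append(f"chi2_pvalue\t{self.chi2_pvalue:.6g}")
        lines.append(f"binomial_depletion_pvalue\t{self.binomial_depletion_pvalue:.6g}")
        return "\n".join(lines) + "\n"


def compartment_enrichment(
    calls: DomainCallSet | list[tuple[int, int]],
    assignment: CompartmentAssignment,
) -> EnrichmentReport:
    """Test whether significant domain pairs prefer same-compartment partners.

    Expected proportions over unordered pairs are p^2 : n^2 : 2pn
    (normalized), with p/n the counts of positive/negative domains.  Emits a
    2-df chi-square goodness-of-fit test and a one-sided binomial test for
    depletion of mixed (+-) pairs.  Pairs involving unclassified domains are
    excluded.
    """
    n_pos, n_neg = assignment.counts()
    if n_pos + n_neg < 2:
        raise ValueError("need at least 2 classified domains")
    pairs = calls.calls if isinstance(calls, DomainCallSet) else calls
    observed = {"++": 0, "--": 0, "+-": 0}
    for pair in pairs:
        i, j = (pair.i, pair.j) if hasattr(pair, "i") else pair
        li, lj = assignment.labels[i], assignment.labels[j]
        if li == 0 or lj == 0:
            continue
        if li == 1 and lj == 1:
            observed["++"] += 1
        elif li == -1 and lj == -1:
            observed["--"] += 1
        else:
            observed["+-"] += 1
    n_pairs = sum(observed.values())
    if n_pairs == 0:
        raise ValueError("no significant pairs between classified domains")

    weights = {"++": n_pos ** 2, "--": n_neg ** 2, "+-": 2 * n_pos * n_neg}
    total = sum(weights.values())
    expected_prop = {k: w / total for k, w in weights.items()}
    expected_cnt = {k: v * n_pairs for k, v in expected_prop.items()}

    keys = ("++", "--", "+-")
    obs_arr = np.array([observed[k] for k in keys], dtype=float)
    exp_arr = np.array([expected_cnt[k] for k in keys])
    usable = exp_arr > 0
    chi2_stat, chi2_p = stats.chisquare(obs_arr[usable], exp_arr[usable])

    p_mixed = expected_prop["+-"]
    binom_p = float(stats.binom.cdf(observed["+-"], n_pairs, p_mixed)) if p_mixed > 0 else 1.0

    return EnrichmentReport(
        observed=observed,
        expected_proportions=expected_prop,
        expected_counts=expected_cnt,
        chi2_statistic=float(chi2_stat),
        chi2_pvalue=float(chi2_p),
        binomial_depletion_pvalue=binom_p,
        n_pairs=n_pairs,
        n_positive_domains=n_pos,
        n_negative_domains=n_neg,
    )
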