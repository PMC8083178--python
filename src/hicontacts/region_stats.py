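"""Region-mode statistics: interaction profiles against a distance-matched
Weibull background, BH-FDR, replicate intersection and call clustering.

For each genomic distance ``d`` (in bins) the strictly positive values of the
map's d-th diagonal are fitted with a two-parameter Weibull by maximum
likelihood; the fraction of zeros ``z_d`` is folded into the upper-tail
p-value as a point mass, so that

    p(x) = 1                          if x == 0
    p(x) = (1 - z_d) * exp(-(x / lambda_d) ** k_d)   otherwise.

All (anchor, offset) tests of one replicate on one chromosome form a single
BH family; a call is significant only when q <= alpha in every replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .hic_io import Call, CallSet, HiCMap, Region

logger = logging.getLogger(__name__)

__all__ = [
    "BackgroundEntry",
    "WeibullBackground",
    "InteractionProfile",
    "Cluster",
    "fit_weibull_mle",
    "fit_weibull_moments",
    "extract_profile",
    "fit_background",
    "profile_pvalues",
    "bh_fdr",
    "call_interactions",
    "cluster_consecutive",
]

DEFAULT_WINDOW = 30     # bins each way
DEFAULT_ALPHA = 0.01
DEFAULT_MIN_SAMPLES = 50
FIT_MAX_ITER = 200
FIT_TOL = 1e-8


# ---------------------------------------------------------------------------
# Weibull fitting
# ---------------------------------------------------------------------------

def fit_weibull_moments(x: np.ndarray) -> tuple[float, float]:
    """Method-of-moments estimate of Weibull (shape, scale).

    Solves CV(k) = sd/mean from the identity
    CV^2 = Gamma(1 + 2/k) / Gamma(1 + 1/k)^2 - 1, then scale from the mean.
    """
    x = np.asarray(x, dtype=float)
    mean, sd = x.mean(), x.std()
    if sd == 0 or mean <= 0:
        raise ValueError("degenerate sample: zero variance")
    target = (sd / mean) ** 2

    def cv2(k: float) -> float:
        return special.gamma(1 + 2 / k) / special.gamma(1 + 1 / k) ** 2 - 1 - target

    k = optimize.brentq(cv2, 0.05, 50.0, xtol=FIT_TOL, maxiter=FIT_MAX_ITER)
    lam = mean / special.gamma(1 + 1 / k)
    return float(k), float(lam)


def fit_weibull_mle(
    x: np.ndarray,
    max_iter: int = FIT_MAX_ITER,
    tol: float = FIT_TOL,
) -> tuple[float, float]:
    """Maximum-likelihood fit of a two-parameter Weibull to positive samples.

    Solves the profile score equation for the shape
    ``sum(x^k ln x)/sum(x^k) - 1/k - mean(ln x) = 0`` (monotone in k) by
    bracketed root finding, then ``scale = mean(x^k) ** (1/k)``.  Falls back
    to method of moments if root finding fails.
    """
    x = np.asarray(x, dtype=float)
    if (x <= 0).any():
        raise ValueError("Weibull MLE requires strictly positive samples")
    if x.std() == 0:
        raise ValueError("degenerate sample: zero variance")
    lx = np.log(x)
    mean_lx = lx.mean()

    def score(k: float) -> float:
        # shift x^k by max for numerical stability at large k
        w = np.exp(k * (lx - lx.max()))
        return float((w @ lx) / w.sum() - 1.0 / k - mean_lx)

    lo, hi = 1e-2, 1.0
    for _ in range(60):
        if score(hi) > 0:
            break
        hi *= 2.0
    try:
        k = optimize.brentq(score, lo, hi, xtol=tol, maxiter=max_iter)
    except (ValueError, RuntimeError):
        logger.warning("Weibull MLE failed to converge; using method of moments")
        return fit_weibull_moments(x)
    lam = float(np.exp(lx.max()) * (np.exp(k * (lx - lx.max())).mean()) ** (1.0 / k))
    return float(k), lam


# ---------------------------------------------------------------------------
# background model
# ---------------------------------------------------------------------------

@dataclass
class BackgroundEntry:
    """Fitted Weibull null for one bin distance."""

    distance: int
    shape: float = np.nan
    scale: float = np.nan
    zero_fraction: float = 0.0
    n_total: int = 0
    n_positive: int = 0
    usable: bool = False


@dataclass
class WeibullBackground:
    """Per-distance Weibull null model for one chromosome map."""

    chromosome: str
    entries: dict[int, BackgroundEntry] = field(default_factory=dict)

    def __getitem__(self, d: int) -> BackgroundEntry:
        return self.entries[d]

    def usable_distances(self) -> list[int]:
        return sorted(d for d, e in self.entries.items() if e.usable)


def fit_background(
    hic: HiCMap,
    window: int = DEFAULT_WINDOW,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> WeibullBackground:
    """Fit the distance-matched Weibull null for distances 1..window.

    The fit uses only the strictly positive diagonal values; the zero
    fraction is recorded per distance.  Distances with fewer than
    ``min_samples`` positive values, or with zero variance, are flagged
    unusable (p-values there stay missing).
    """
    bg = WeibullBackground(chromosome=hic.chromosome)
    m = hic.matrix
    for d in range(1, window + 1):
        entry = BackgroundEntry(distance=d)
        if d < hic.n_bins:
            diag = np.diagonal(m, d)
            pos = diag[diag > 0]
            entry.n_total = diag.size
            entry.n_positive = pos.size
            entry.zero_fraction = 1.0 - pos.size / diag.size if diag.size else 1.0
            if pos.size >= min_samples and pos.std() > 0:
                try:
                    entry.shape, entry.scale = fit_weibull_mle(pos)
                    entry.usable = True
                except ValueError:
                    logger.warning("distance %d: degenerate diagonal, flagged unusable", d)
        bg.entries[d] = entry
    n_unusable = sum(not e.usable for e in bg.entries.values())
    if n_unusable:
        logger.info("%s: %d of %d distances unusable (too few positive values)",
                    hic.chromosome, n_unusable, window)
    return bg


# ---------------------------------------------------------------------------
# profiles and p-values
# ---------------------------------------------------------------------------

@dataclass
class InteractionProfile:
    """Horizontal contact profile of one anchor over offsets -D..-1, 1..D.

    ``offsets[i]`` is the signed bin offset of position i; missing positions
    (off-chromosome, or untestable background) carry NaN.
    """

    anchor: Region
    window: int
    offsets: np.ndarray          # signed ints, length 2*window
    intensity: np.ndarray        # float, NaN = missing
    p: np.ndarray | None = None
    q: np.ndarray | None = None

    def partner_bin(self, i: int) -> int:
        off = int(self.offsets[i])
        base = self.anchor.bin_start if off < 0 else self.anchor.bin_end
        return base + off


def extract_profile(hic: HiCMap, anchor: Region, window: int = DEFAULT_WINDOW) -> InteractionProfile:
    """Extract horizontal intensities left and right of the anchor.

    Multi-bin anchors use the element-wise mean of their constituent rows.
    Offsets are measured from the anchor's outermost bin on each side, so
    offset +-1 is the bin immediately adjacent to the region.  Positions
    beyond the map are NaN (missing), not zero.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if anchor.bin_start < 0 or anchor.bin_end >= hic.n_bins:
        raise ValueError(
            f"anchor {anchor.name} bins [{anchor.bin_start},{anchor.bin_end}] "
            f"outside map with {hic.n_bins} bins"
        )
    row = hic.matrix[anchor.bin_start: anchor.bin_end + 1].mean(axis=0)
    offsets = np.concatenate([np.arange(-window, 0), np.arange(1, window + 1)])
    intensity = np.full(offsets.size, np.nan)
    for i, off in enumerate(offsets):
        pos = (anchor.bin_start if off < 0 else anchor.bin_end) + off
        if 0 <= pos < hic.n_bins:
            intensity[i] = row[pos]
    return InteractionProfile(anchor=anchor, window=window, offsets=offsets,
                              intensity=intensity)


def weibull_tail_p(x: float, entry: BackgroundEntry) -> float:
    """Zero-inflated Weibull upper-tail p-value for one intensity."""
    if x < 0:
        raise ValueError(f"negative intensity {x}")
    if x == 0:
        return 1.0
    return (1.0 - entry.zero_fraction) * float(
        np.exp(-((x / entry.scale) ** entry.shape))
    )


def profile_pvalues(profile: InteractionProfile, bg: WeibullBackground) -> InteractionProfile:
    """Fill in upper-tail p-values for every testable profile position."""
    p = np.full(profile.offsets.size, np.nan)
    for i, off in enumerate(profile.offsets):
        x = profile.intensity[i]
        if np.isnan(x):
            continue
        d = abs(int(off))
        entry = bg.entries.get(d)
        if entry is None or not entry.usable:
            continue
        p[i] = weibull_tail_p(x, entry)
    profile.p = p
    return profile


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    Missing entries (NaN) are excluded from the family size m and stay NaN.
    Uses a stable sort, so tied p-values receive identical q-values.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    flat = p.ravel()
    mask = ~np.isnan(flat)
    pv = flat[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    q = np.maximum(q, pv)   # guard 1-ulp rounding below p in p*m/j
    flat_out = out.ravel()
    flat_out[mask] = q
    return flat_out.reshape(p.shape)


# ---------------------------------------------------------------------------
# calling and clustering
# ---------------------------------------------------------------------------

def call_interactions(
    maps: list[HiCMap],
    anchors: list[Region],
    window: int = DEFAULT_WINDOW,
    alpha: float = DEFAULT_ALPHA,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> tuple[CallSet, list[list[InteractionProfile]]]:
    """Run the full region pipeline over one or more replicate maps.

    Per replicate: fit the background, compute p-values for all anchors,
    then BH-correct jointly over every (anchor, offset) test of the
    chromosome.  A call is flagged iff q <= alpha in *every* replicate.

    Returns the call set and, per replicate, the list of profiles (with p
    and q filled) in anchor order.
    """
    if not maps:
        raise ValueError("at least one replicate map required")
    if not 0 <= alpha < 1:
        raise ValueError(f"alpha must lie in [0, 1), got {alpha}")
    shapes = {m.matrix.shape for m in maps}
    if len(shapes) > 1:
        raise ValueError(f"replicate maps differ in shape: {shapes}")
    if len({m.resolution for m in maps}) > 1:
        raise ValueError("replicate maps differ in resolution")

    all_profiles: list[list[InteractionProfile]] = []
    p_stack = []   # (n_reps, n_anchors, 2*window)
    for hic in maps:
        bg = fit_background(hic, window=window, min_samples=min_samples)
        profiles = [profile_pvalues(extract_profile(hic, a, window), bg) for a in anchors]
        all_profiles.append(profiles)
        p_stack.append(np.array([pr.p for pr in profiles]))

    q_stack = []
    for rep, pmat in enumerate(p_stack):
        qmat = bh_fdr(pmat)
        q_stack.append(qmat)
        for i, pr in enumerate(all_profiles[rep]):
            pr.q = qmat[i]

    q_arr = np.array(q_stack)   # (reps, anchors, positions)
    p_arr = np.array(p_stack)
    with np.errstate(invalid="ignore"):
        sig = (q_arr <= alpha).all(axis=0) & ~np.isnan(q_arr).any(axis=0)

    calls: list[Call] = []
    ref = all_profiles[0]
    for i, j in zip(*np.nonzero(sig)):
        pr = ref[i]
        calls.append(Call(
            anchor_name=pr.anchor.name,
            anchor_bin=pr.anchor.bin_start,
            partner_bin=pr.partner_bin(j),
            p=float(p_arr[:, i, j].max()),
            q=float(q_arr[:, i, j].max()),
            rep_p=tuple(float(v) for v in p_arr[:, i, j]),
            rep_q=tuple(float(v) for v in q_arr[:, i, j]),
        ))
    callset = CallSet(chromosome=maps[0].chromosome, resolution=maps[0].resolution,
                      calls=calls, alpha=alpha)
    return callset, all_profiles


@dataclass
class Cluster:
    """A maximal run of consecutive partner bins for one anchor."""

    anchor_name: str
    anchor_bin: int
    partner_start_bin: int
    partner_end_bin: int   # inclusive
    size: int
    min_q: float


def cluster_consecutive(calls: CallSet) -> list[Cluster]:
    """Merge same-anchor calls whose partner bins are consecutive integers."""
    by_anchor: dict[tuple[str, int], list[Call]] = {}
    for c in calls.calls:
        by_anchor.setdefault((c.anchor_name, c.anchor_bin), []).append(c)
    clusters: list[Cluster] = []
    for (name, abin), group in sorted(by_anchor.items()):
        group = sorted({c.partner_bin: c for c in group}.items())
        run: list[tuple[int, Call]] = []
        for bin_, call in group:
            if run and bin_ != run[-1][0] + 1:
                clusters.append(_make_cluster(name, abin, run))
                run = []
            run.append((bin_, call))
        if run:
            clusters.append(_make_cluster(name, abin, run))
    return clusters


def _make_cluster(name: str, abin: int, run: list[tuple[int, Call]]) -> Cluster:
    bins = [b for b, _ in run]
    return Cluster(
        anchor_name=name,
        anchor_bin=abin,
        partner_start_bin=bins[0],
        partner_end_bin=bins[-1],
        size=len(bins),
        min_q=min(c.q for _, c in run),
    )
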