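"""Cross-tool comparison machinery: exact and tolerance-based intersection
of call lists, overlap significance, and ChIP-seq peak enrichment of called
partner bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .hic_io import CallSet, HiCMap, Region, bin_to_bp

logger = logging.getLogger(__name__)

__all__ = [
    "GenericCallList",
    "IntersectionResult",
    "PeakEnrichmentReport",
    "read_generic_calls",
    "tolerant_intersection",
    "overlap_significance",
    "peak_enrichment",
]


@dataclass
class GenericCallList:
    """Deduplicated (anchor bin, partner bin) pairs from one tool."""

    tool: str
    chromosome: str
    resolution: int
    pairs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        dedup = sorted(set(map(tuple, self.pairs)))
        if any(a < 0 or b < 0 for a, b in dedup):
            raise ValueError("bins must be non-negative")
        self.pairs = dedup

    @classmethod
    def from_callset(cls, calls: CallSet, tool: str = "hicontacts") -> "GenericCallList":
        return cls(tool=tool, chromosome=calls.chromosome, resolution=calls.resolution,
                   pairs=[(c.anchor_bin, c.partner_bin) for c in calls.calls])


def read_generic_calls(path: str | Path, resolution: int, tool: str = "other") -> GenericCallList:
    """Read the adapter TSV: chrom, anchor_start, anchor_end, partner_start, partner_end."""
    path = Path(path)
    pairs = []
    chrom = ""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(f)}")
            chrom = f[0]
            pairs.append((int(f[1]) // resolution, int(f[3]) // resolution))
    return GenericCallList(tool=tool, chromosome=chrom, resolution=resolution, pairs=pairs)


@dataclass
class IntersectionResult:
    matched: list[tuple[tuple[int, int], tuple[int, int]]]
    n_matched: int
    n_a_only: int
    n_b_only: int


def tolerant_intersection(a: GenericCallList, b: GenericCallList, tol: int = 0) -> IntersectionResult:
    """One-to-one matching of call pairs within +-tol bins on both coordinates.

    Candidate matches are consumed greedily in order of increasing total bin
    distance (ties by lower partner bin, then anchor bin) so one call cannot
    absorb several matches.
    """
    if a.resolution != b.resolution:
        raise ValueError(f"resolution mismatch: {a.resolution} vs {b.resolution}")
    if tol < 0:
        raise ValueError("tolerance must be >= 0")
    candidates = []
    for pa in a.pairs:
        for pb in b.pairs:
            da, dp = abs(pa[0] - pb[0]), abs(pa[1] - pb[1])
            if da <= tol and dp <= tol:
                candidates.append((da + dp, min(pa[1], pb[1]), min(pa[0], pb[0]), pa, pb))
    candidates.sort()
    used_a: set[tuple[int, int]] = set()
    used_b: set[tuple[int, int]] = set()
    matched = []
    for _, _, _, pa, pb in candidates:
        if pa in used_a or pb in used_b:
            continue
        used_a.add(pa)
        used_b.add(pb)
        matched.append((pa, pb))
    return IntersectionResult(
        matched=matched,
        n_matched=len(matched),
        n_a_only=len(a.pairs) - len(matched),
        n_b_only=len(b.pairs) - len(matched),
    )


def overlap_significance(n_common: int, n_a: int, n_b: int, universe: int) -> float:
    """One-sided binomial p-value for the overlap of two call sets.

    X ~ Binomial(n_a, n_b / universe); returns P(X >= n_common).
    """
    if universe <= 0:
        raise ValueError("universe must be positive")
    if n_common > min(n_a, n_b):
        raise ValueError(f"n_common {n_common} exceeds min(n_a, n_b) = {min(n_a, n_b)}")
    if n_a > universe or n_b > universe:
        raise ValueError("call counts cannot exceed the universe")
    rate = n_b / universe
    return float(stats.binom.sf(n_common - 1, n_a, rate))


def _bins_overlapping_peaks(
    bins: np.ndarray, peaks: list[tuple[str, int, int]], chromosome: str, resolution: int,
) -> np.ndarray:
    """Boolean mask: does each bin's bp interval intersect any peak?"""
    chrom_peaks = sorted((s, e) for c, s, e in peaks if c == chromosome)
    if not chrom_peaks:
        return np.zeros(bins.size, dtype=bool)
    starts = np.array([s for s, _ in chrom_peaks])
    ends = np.array([e for _, e in chrom_peaks])
    out = np.zeros(bins.size, dtype=bool)
    for idx, b in enumerate(bins):
        lo, hi = bin_to_bp(int(b), resolution)
        j = np.searchsorted(starts, hi)   # peaks starting before bin end
        out[idx] = bool((ends[:j] > lo).any())
    return out


@dataclass
class PeakEnrichmentReport:
    n_called_bins: int
    n_called_in_peaks: int
    n_queried_bins: int
    n_queried_in_peaks: int
    background_rate: float
    pvalue: float
    depleted: bool


def peak_enrichment(
    calls: CallSet,
    peaks: list[tuple[str, int, int]],
    hic: HiCMap,
    anchors: list[Region],
    window: int,
) -> PeakEnrichmentReport:
    """Binomial enrichment of called partner bins in ChIP-seq peaks.

    The background rate is the fraction of *queried* bins — every bin tested
    in the region run (anchors x window positions, on-chromosome) — whose bp
    interval intersects at least one peak.  The test is one-sided binomial
    on the deduplicated called partner bins.
    """
    if not peaks:
        raise ValueError("empty peak list")
    queried: set[int] = set()
    for a in anchors:
        for off in range(-window, window + 1):
            if off == 0:
                continue
            pos = (a.bin_start if off < 0 else a.bin_end) + off
            if 0 <= pos < hic.n_bins:
                queried.add(pos)
    queried_arr = np.array(sorted(queried))
    q_mask = _bins_overlapping_peaks(queried_arr, peaks, calls.chromosome, calls.resolution)
    rate = float(q_mask.mean()) if queried_arr.size else 0.0

    called_bins = np.array(sorted({c.partner_bin for c in calls.calls}))
    c_mask = _bins_overlapping_peaks(called_bins, peaks, calls.chromosome, calls.resolution)
    n_called, n_hit = int(called_bins.size), int(c_mask.sum())

    if rate >= 1.0:
        p = 1.0
    elif rate <= 0.0:
        p = 1.0 if n_hit == 0 else 0.0
    else:
        p = float(stats.binom.sf(n_hit - 1, n_called, rate)) if n_called else 1.0
    depleted = n_called > 0 and n_hit < rate * n_called
    if depleted:
        logger.info("called bins overlap peaks below background rate (depletion)")
    return PeakEnrichmentReport(
        n_called_bins=n_called,
        n_called_in_peaks=n_hit,
        n_queried_bins=int(queried_arr.size),
        n_queried_in_peaks=int(q_mask.sum()),
        background_rate=rate,
        pvalue=p,
        depleted=depleted,
    )
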