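"""Synthetic cis Hi-C maps with known ground truth.

Null model: the entry at bin distance d is drawn from a Weibull with shape
k(d) and scale lambda(d) = lambda0 * d**(-gamma) (d >= 1; the main diagonal
uses lambda0), then zeroed with probability z(d).  Planted loops, domains,
domain-pair blocks and compartments multiply the scale of the cells they
cover; the upper triangle is generated and mirrored.  A lognormal noise
option exists to probe model misspecification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hic_io import HiCMap, save_map

__all__ = [
    "PlantedLoop",
    "PlantedBlock",
    "SyntheticSpec",
    "GroundTruth",
    "generate_map",
    "generate_fixtures",
]


@dataclass
class PlantedLoop:
    """A single enriched pixel.

    mode "scale": the pixel is drawn from the null with its scale multiplied
    by ``fold`` (stochastic).  mode "fixed": the pixel is set to
    ``fold * lambda(d)`` exactly (deterministic enrichment).
    """

    bin_a: int
    bin_b: int
    fold: float
    mode: str = "scale"

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold must be positive")
        if self.mode not in ("scale", "fixed"):
            raise ValueError(f"unknown loop mode {self.mode!r}")


@dataclass
class PlantedBlock:
    """An enriched rectangle between two bin ranges (inclusive ends)."""

    range_i: tuple[int, int]
    range_j: tuple[int, int]
    fold: float

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold must be positive")


@dataclass
class SyntheticSpec:
    """Parameters of the null decay model and the planted signals."""

    n_bins: int
    seed: int
    shape: float = 1.5
    lambda0: float = 100.0
    gamma: float = 1.0
    zero_inflation: float = 0.0
    loops: list[PlantedLoop] = field(default_factory=list)
    domains: list[tuple[tuple[int, int], float]] = field(default_factory=list)
    blocks: list[PlantedBlock] = field(default_factory=list)
    compartment_labels: np.ndarray | None = None
    compartment_fold: float = 1.0
    noise: str = "weibull"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must lie in [0, 1)")
        if self.noise not in ("weibull", "lognormal"):
            raise ValueError(f"unknown noise family {self.noise!r}")
        n = self.n_bins
        for loop in self.loops:
            if not (0 <= loop.bin_a < n and 0 <= loop.bin_b < n):
                raise ValueError(f"loop ({loop.bin_a},{loop.bin_b}) outside map")
        for (lo, hi), fold in self.domains:
            if not (0 <= lo <= hi < n):
                raise ValueError(f"domain range ({lo},{hi}) outside map")
            if fold <= 0:
                raise ValueError("fold must be positive")
        for blk in self.blocks:
            for lo, hi in (blk.range_i, blk.range_j):
                if not (0 <= lo <= hi < n):
                    raise ValueError(f"block range ({lo},{hi}) outside map")
        if self.compartment_labels is not None:
            labels = np.asarray(self.compartment_labels)
            if labels.shape != (n,):
                raise ValueError("compartment_labels must have one label per bin")
            self.compartment_labels = labels

    def scale_at(self, d: int) -> float:
        return self.lambda0 * (max(d, 1) ** -self.gamma)


@dataclass
class GroundTruth:
    """Every planted coordinate, sufficient to score recall/precision."""

    loops: list[tuple[int, int]]
    blocks: list[tuple[tuple[int, int], tuple[int, int]]]
    domains: list[tuple[int, int]]
    compartment_labels: np.ndarray | None


def _fold_matrix(spec: SyntheticSpec) -> np.ndarray:
    n = spec.n_bins
    fold = np.ones((n, n))
    for (lo, hi), f in spec.domains:
        fold[lo:hi + 1, lo:hi + 1] *= f
    for blk in spec.blocks:
        (ilo, ihi), (jlo, jhi) = blk.range_i, blk.range_j
        fold[ilo:ihi + 1, jlo:jhi + 1] *= blk.fold
        fold[jlo:jhi + 1, ilo:ihi + 1] *= blk.fold
    if spec.compartment_labels is not None and spec.compartment_fold != 1.0:
        same = spec.compartment_labels[:, None] == spec.compartment_labels[None, :]
        fold[same] *= spec.compartment_fold
    for loop in spec.loops:
        if loop.mode == "scale":
            fold[loop.bin_a, loop.bin_b] *= loop.fold
            fold[loop.bin_b, loop.bin_a] *= loop.fold
    return fold


def generate_map(
    spec: SyntheticSpec,
    chromosome: str = "chrS",
    resolution: int = 10_000,
) -> tuple[HiCMap, GroundTruth]:
    """Draw one synthetic map and its ground-truth record."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_bins
    fold = _fold_matrix(spec)
    m = np.zeros((n, n))
    for d in range(n):
        lam = spec.scale_at(d)
        idx = (np.arange(n - d), np.arange(d, n))
        scale = lam * fold[idx]
        if spec.noise == "weibull":
            vals = scale * rng.weibull(spec.shape, size=n - d)
        else:
            # lognormal matched to the Weibull's mean at sigma=0.5
            mean = scale * math.gamma(1 + 1 / spec.shape)
            vals = rng.lognormal(np.log(mean) - 0.125, 0.5)
        if spec.zero_inflation > 0:
            vals = np.where(rng.random(n - d) < spec.zero_inflation, 0.0, vals)
        m[idx] = vals
    for loop in spec.loops:
        if loop.mode == "fixed":
            a, b = sorted((loop.bin_a, loop.bin_b))
            m[a, b] = loop.fold * spec.scale_at(b - a)
    iu = np.triu_indices(n, k=1)
    m[iu[1], iu[0]] = m[iu]

    truth = GroundTruth(
        loops=[tuple(sorted((lp.bin_a, lp.bin_b))) for lp in spec.loops],
        blocks=[(blk.range_i, blk.range_j) for blk in spec.blocks],
        domains=[rng_ for rng_, _ in spec.domains],
        compartment_labels=(None if spec.compartment_labels is None
                            else spec.compartment_labels.copy()),
    )
    return HiCMap(chromosome=chromosome, resolution=resolution, matrix=m), truth


# ---------------------------------------------------------------------------
# standard fixture scenarios
# ---------------------------------------------------------------------------

FIXTURE_RESOLUTION = 10_000


def _write_bed(path: Path, rows: list[tuple[str, int, int, str]]) -> None:
    path.write_text("".join(f"{c}\t{s}\t{e}\t{n}\n" for c, s, e, n in rows))


def generate_fixtures(outdir: str | Path, n_bins: int = 120, seed: int = 7) -> dict[str, Path]:
    """Write the standard scenario set as plain-text files.

    Scenarios: a null map, a two-replicate loop map pair with an anchor BED,
    a domain-block map with a domain border file, and a two-compartment map
    with its domain file.  Deterministic for fixed (n_bins, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = FIXTURE_RESOLUTION
    manifest: dict[str, Path] = {}

    null_spec = SyntheticSpec(n_bins=n_bins, seed=seed, shape=2.0)
    null_map, _ = generate_map(null_spec, chromosome="chrS", resolution=res)
    manifest["null_map"] = outdir / "null_map.txt"
    save_map(null_map, manifest["null_map"])

    anchor_bin = n_bins // 3
    partner_bin = anchor_bin + 12
    loops = [PlantedLoop(anchor_bin, partner_bin, fold=12.0, mode="fixed")]
    for rep in (1, 2):
        spec = SyntheticSpec(n_bins=n_bins, seed=seed + rep, shape=2.0, loops=loops)
        rep_map, _ = generate_map(spec, chromosome="chrS", resolution=res)
        key = f"loop_rep{rep}"
        manifest[key] = outdir / f"loop_rep{rep}.txt"
        save_map(rep_map, manifest[key])
    manifest["anchors_bed"] = outdir / "anchors.bed"
    _write_bed(manifest["anchors_bed"],
               [("chrS", anchor_bin * res, (anchor_bin + 1) * res, "anchor1")])

    n_dom = max(4, n_bins // 15)
    dom_size = n_bins // n_dom
    dom_ranges = [(k * dom_size, min((k + 1) * dom_size, n_bins) - 1) for k in range(n_dom)]
    # flat decay: the product-margin domain null is exact-model on this map
    block = PlantedBlock(dom_ranges[0], dom_ranges[n_dom - 2], fold=10.0)
    spec = SyntheticSpec(n_bins=n_bins, seed=seed + 10, shape=2.0, gamma=0.0,
                         blocks=[block])
    block_map, _ = generate_map(spec, chromosome="chrS", resolution=res)
    manifest["domain_block_map"] = outdir / "domain_block_map.txt"
    save_map(block_map, manifest["domain_block_map"])
    manifest["domains_bed"] = outdir / "domains.bed"
    _write_bed(manifest["domains_bed"],
               [("chrS", lo * res, (hi + 1) * res, "0") for lo, hi in dom_ranges])

    labels = (np.arange(n_bins) // (n_bins // 8)) % 2
    spec = SyntheticSpec(n_bins=n_bins, seed=seed + 20, shape=2.0,
                         compartment_labels=labels, compartment_fold=3.0)
    comp_map, _ = generate_map(spec, chromosome="chrS", resolution=res)
    manifest["compartment_map"] = outdir / "compartment_map.txt"
    save_map(comp_map, manifest["compartment_map"])
    manifest["compartment_domains_bed"] = outdir / "compartment_domains.bed"
    blocks_of_8 = n_bins // 8
    _write_bed(manifest["compartment_domains_bed"],
               [("chrS", k * blocks_of_8 * res, (k + 1) * blocks_of_8 * res, "0")
                for k in range(8)])
    return manifest
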