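"""Plotting: per-anchor interaction profile figures and the triangular
map/q-value figure for domain runs.  Matplotlib only; plots are pure side
effects and never alter numerical results.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .domain_stats import DomainCallSet
from .hic_io import HiCMap
from .region_stats import InteractionProfile

__all__ = ["plot_profile", "plot_domain_map"]


def plot_profile(
    profile: InteractionProfile,
    alpha: float,
    path: str | Path,
    title: str | None = None,
    formats: tuple[str, ...] = ("png", "svg"),
) -> list[Path]:
    """Plot distance-weighted intensities and -log10 q for one anchor.

    The intensity track shows intensity * |offset| (display-only weighting);
    the significance track shows -log10 q with a horizontal threshold line
    at -log10 alpha.
    """
    path = Path(path)
    offs = profile.offsets
    weighted = profile.intensity * np.abs(offs)
    q = profile.q if profile.q is not None else np.full(offs.size, np.nan)
    with np.errstate(divide="ignore"):
        neglog_q = -np.log10(q)

    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(8, 5))
    ax1.bar(offs, np.nan_to_num(weighted), color="steelblue", width=0.8)
    ax1.set_ylabel("intensity x |offset|")
    ax1.set_title(title or f"anchor {profile.anchor.name}")
    ax2.bar(offs, np.nan_to_num(neglog_q), color="darkorange", width=0.8)
    ax2.axhline(-np.log10(alpha), color="red", linestyle="--", linewidth=1,
                label=f"alpha = {alpha:g}")
    ax2.set_ylabel("-log10 q")
    ax2.set_xlabel("offset from anchor (bins)")
    ax2.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    written = []
    for fmt in formats:
        out = path.with_suffix(f".{fmt}")
        fig.savefig(out, dpi=120)
        written.append(out)
    plt.close(fig)
    return written


def plot_domain_map(
    hic: HiCMap,
    callset: DomainCallSet,
    path: str | Path,
    title: str | None = None,
    ticks: int = 10,
    map_cmap: str = "Reds",
    sig_cmap: str = "Blues",
    formats: tuple[str, ...] = ("png", "svg"),
) -> list[Path]:
    """Triangular figure: raw map in the upper triangle, -log10 q of domain
    pairs as filled blocks in the lower triangle."""
    path = Path(path)
    n = hic.n_bins
    upper = np.full((n, n), np.nan)
    iu = np.triu_indices(n)
    upper[iu] = hic.matrix[iu]

    lower = np.full((n, n), np.nan)
    doms = callset.domains
    with np.errstate(divide="ignore"):
        for i in range(len(doms)):
            for j in range(i + 1, len(doms)):
                qv = callset.q_matrix[i, j]
                if np.isnan(qv):
                    continue
                val = min(1000.0, -np.log10(qv)) if qv > 0 else 1000.0
                di, dj = doms[i], doms[j]
                lower[dj.bin_start:dj.bin_end + 1, di.bin_start:di.bin_end + 1] = val

    fig, ax = plt.subplots(figsize=(7, 6))
    im1 = ax.imshow(upper, cmap=map_cmap, interpolation="none")
    im2 = ax.imshow(lower, cmap=sig_cmap, interpolation="none")
    fig.colorbar(im1, ax=ax, fraction=0.045, label="contacts")
    fig.colorbar(im2, ax=ax, fraction=0.045, label="-log10 q")
    tick_pos = np.arange(0, n, max(1, ticks))
    ax.set_xticks(tick_pos)
    ax.set_yticks(tick_pos)
    ax.set_title(title or f"{hic.chromosome} domain interactions ({callset.test})")
    fig.tight_layout()
    written = []
    for fmt in formats:
        out = path.with_suffix(f".{fmt}")
        fig.savefig(out, dpi=120)
        written.append(out)
    plt.close(fig)
    return written
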