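"""Input/output for cis Hi-C maps, interval files, call sets and liftover.

All genomic coordinates are 0-based half-open base pairs; bin indices are
0-based and a bin ``b`` at resolution ``res`` covers ``[b*res, (b+1)*res)``.
Output BED is 0-based half-open, output GFF is 1-based inclusive.
"""

from __future__ import annotations

import logging
import math
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "HiCMap",
    "Region",
    "Domain",
    "Call",
    "CallSet",
    "FormatError",
    "DataError",
    "load_map",
    "save_map",
    "read_regions_bed",
    "read_enhancer_fasta",
    "read_domains",
    "read_peaks_bed",
    "write_calls",
    "read_calls",
    "liftover_calls",
    "bp_to_bin",
    "bin_to_bp",
]

MAX_REGION_BINS = 3
SYMMETRY_TOL = 1e-9


class FormatError(ValueError):
    """Raised when an input file does not conform to its expected format."""


class DataError(ValueError):
    """Raised when file contents are well-formed but semantically invalid."""


def bp_to_bin(pos: int, resolution: int) -> int:
    """Map a base-pair position to the bin containing it."""
    return pos // resolution


def bin_to_bp(b: int, resolution: int) -> tuple[int, int]:
    """Base-pair interval (half-open) covered by bin ``b``."""
    return b * resolution, (b + 1) * resolution


@dataclass
class HiCMap:
    """One chromosome's symmetric cis contact matrix.

    Attributes
    ----------
    chromosome : str
        Chromosome label, e.g. ``"chr1"``.
    resolution : int
        Base pairs per bin.
    matrix : numpy.ndarray
        Square, symmetric, non-negative matrix of contact counts.
    """

    chromosome: str
    resolution: int
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise FormatError(f"contact matrix must be square, got shape {m.shape}")
        if self.resolution <= 0:
            raise DataError(f"resolution must be positive, got {self.resolution}")
        self.matrix = m

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]


@dataclass
class Region:
    """A short region of interest (1-3 bins at the map resolution)."""

    chromosome: str
    start: int
    end: int
    name: str = "."
    bin_start: int = field(default=-1)
    bin_end: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise DataError(
                f"region {self.name}: start {self.start} must be < end {self.end}"
            )

    def assign_bins(self, resolution: int) -> "Region":
        self.bin_start = bp_to_bin(self.start, resolution)
        self.bin_end = bp_to_bin(self.end - 1, resolution)
        return self

    @property
    def n_bins(self) -> int:
        return self.bin_end - self.bin_start + 1

    @property
    def bins(self) -> range:
        return range(self.bin_start, self.bin_end + 1)


@dataclass
class Domain:
    """A chromosomal domain (e.g. a TAD) with optional hierarchy level."""

    chromosome: str
    start: int
    end: int
    level: int = 0
    bin_start: int = field(default=-1)
    bin_end: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise DataError(f"domain start {self.start} must be < end {self.end}")
        if self.level < 0:
            raise DataError(f"domain level must be >= 0, got {self.level}")

    def assign_bins(self, resolution: int) -> "Domain":
        self.bin_start = bp_to_bin(self.start, resolution)
        self.bin_end = bp_to_bin(self.end - 1, resolution)
        return self

    @property
    def bins(self) -> range:
        return range(self.bin_start, self.bin_end + 1)


@dataclass
class Call:
    """A significant (anchor, partner-bin) contact.

    ``partner_start``/``partner_end`` default to the partner bin's bp
    interval; liftover replaces them with remapped coordinates.
    """

    anchor_name: str
    anchor_bin: int
    partner_bin: int
    p: float
    q: float
    rep_p: tuple[float, ...] = ()
    rep_q: tuple[float, ...] = ()
    significant: bool = True
    partner_start: int | None = None
    partner_end: int | None = None

    def partner_interval(self, resolution: int) -> tuple[int, int]:
        if self.partner_start is not None and self.partner_end is not None:
            return self.partner_start, self.partner_end
        return bin_to_bp(self.partner_bin, resolution)


@dataclass
class CallSet:
    """Significant calls for one chromosome at one resolution."""

    chromosome: str
    resolution: int
    calls: list[Call]
    alpha: float = 0.01

    def __len__(self) -> int:
        return len(self.calls)

    def sorted(self) -> list[Call]:
        return sorted(self.calls, key=lambda c: (c.anchor_name, c.anchor_bin, c.partner_bin))


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------

def load_map(path: str | Path, resolution: int, chromosome: str) -> HiCMap:
    """Load a dense square cis contact matrix from ``.npy`` or text.

    NaN entries are replaced with 0 (count logged).  Asymmetric input is
    symmetrized as ``(M + M.T) / 2`` with a warning.  Negative entries are a
    data error, a non-square matrix a format error.
    """
    path = Path(path)
    if path.suffix == ".npy":
        m = np.load(path)
    else:
        try:
            m = np.loadtxt(path, dtype=float, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: cannot parse as a numeric matrix: {exc}") from exc
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise FormatError(f"{path}: contact matrix must be square, got shape {m.shape}")

    n_nan = int(np.isnan(m).sum())
    if n_nan:
        logger.warning("%s: replaced %d NaN entries with 0", path, n_nan)
        m = np.nan_to_num(m, nan=0.0)
    if (m < 0).any():
        raise DataError(f"{path}: contact matrix contains negative entries")
    asym = np.abs(m - m.T).max() if m.size else 0.0
    if asym > SYMMETRY_TOL:
        logger.warning("%s: matrix asymmetric (max |M-M.T| = %g); symmetrizing", path, asym)
        m = (m + m.T) / 2.0
    return HiCMap(chromosome=chromosome, resolution=resolution, matrix=m)


def save_map(hic: HiCMap, path: str | Path) -> None:
    """Write a map as ``.npy`` or full-precision text (by file suffix)."""
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, hic.matrix)
    else:
        np.savetxt(path, hic.matrix, fmt="%.17g", delimiter="\t")


# ---------------------------------------------------------------------------
# interval files
# ---------------------------------------------------------------------------

def _parse_bed_line(line: str, lineno: int, path: Path) -> tuple[str, int, int, str]:
    fields = line.split()
    if len(fields) < 3:
        raise FormatError(f"{path}:{lineno}: expected >=3 BED fields, got {len(fields)}")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-integer coordinates: {exc}") from exc
    name = fields[3] if len(fields) > 3 else f"{fields[0]}:{start}-{end}"
    return fields[0], start, end, name


def read_regions_bed(path: str | Path, resolution: int) -> list[Region]:
    """Read regions of interest from a BED3+ file and map them to bins.

    Regions spanning more than 3 bins are skipped with a warning.
    """
    path = Path(path)
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name = _parse_bed_line(line, lineno, path)
            region = Region(chrom, start, end, name).assign_bins(resolution)
            if region.n_bins > MAX_REGION_BINS:
                logger.warning(
                    "%s:%d: region %s spans %d bins (> %d); skipped",
                    path, lineno, name, region.n_bins, MAX_REGION_BINS,
                )
                continue
            regions.append(region)
    return regions


_COORD_RE = re.compile(r"(\w+):(\d+)-(\d+)")


def read_enhancer_fasta(path: str | Path, resolution: int) -> list[Region]:
    """Extract regions from FASTA headers carrying ``chrom:start-end`` tokens.

    Sequences are ignored; headers without parseable coordinates are skipped
    with a warning.  The token may appear anywhere in the header line.
    """
    path = Path(path)
    regions: list[Region] = []
    n_skipped = 0
    with open(path) as fh:
        for raw in fh:
            if not raw.startswith(">"):
                continue
            match = _COORD_RE.search(raw[1:])
            if match is None:
                n_skipped += 1
                logger.warning("%s: no coordinates in header %r; skipped", path, raw.strip())
                continue
            chrom, start, end = match.group(1), int(match.group(2)), int(match.group(3))
            region = Region(chrom, start, end, raw[1:].split()[0]).assign_bins(resolution)
            if region.n_bins > MAX_REGION_BINS:
                logger.warning("%s: region %s spans %d bins (> %d); skipped",
                               path, region.name, region.n_bins, MAX_REGION_BINS)
                continue
            regions.append(region)
    if n_skipped:
        logger.warning("%s: skipped %d headers without coordinates", path, n_skipped)
    return regions


def read_domains(
    path: str | Path,
    resolution: int,
    level: int = 0,
    units: str = "bp",
) -> list[Domain]:
    """Read domain borders from a BED-like TSV (chrom, start, end[, level]).

    Only rows matching ``level`` are returned; if the file carries no level
    column all rows are returned.  With ``units="bins"`` coordinates are bin
    indices (half-open) and are scaled by the resolution.  Overlapping
    domains within one level raise a validation error.
    """
    path = Path(path)
    if units not in ("bp", "bins"):
        raise ValueError(f"units must be 'bp' or 'bins', got {units!r}")
    domains: list[Domain] = []
    has_level = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 fields, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
                row_level = int(fields[3]) if len(fields) > 3 else None
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad numeric field: {exc}") from exc
            if has_level is None:
                has_level = row_level is not None
            if units == "bins":
                start, end = start * resolution, end * resolution
            if has_level and row_level != level:
                continue
            domains.append(
                Domain(fields[0], start, end, row_level if row_level is not None else 0
                       ).assign_bins(resolution)
            )
    domains.sort(key=lambda d: d.start)
    offenders = [
        (a.start, a.end, b.start, b.end)
        for a, b in zip(domains, domains[1:])
        if b.start < a.end
    ]
    if offenders:
        raise DataError(f"{path}: overlapping domains at level {level}: {offenders}")
    return domains


def read_peaks_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read ChIP-seq peak intervals from a BED3+ file."""
    path = Path(path)
    peaks = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, _ = _parse_bed_line(line, lineno, path)
            peaks.append((chrom, start, end))
    if not peaks:
        raise DataError(f"{path}: peak file contains no intervals")
    return peaks


# ---------------------------------------------------------------------------
# call sets: txt / BED-like / GFF-like
# ---------------------------------------------------------------------------

_TXT_HEADER = "#anchor_name\tanchor_bin\tpartner_bin\tchrom\tpartner_start\tpartner_end\tp\tq"
_FORMATS = ("txt", "bed", "gff")


def _neg_log10(q: float, cap: float = 1000.0) -> float:
    if q <= 0:
        return cap
    return min(cap, -math.log10(q))


def write_calls(calls: CallSet, fmt: str, path: str | Path) -> None:
    """Write a call set as ``txt``, ``bed`` (BED-like) or ``gff`` (GFF-like).

    Rows are ordered deterministically by (anchor name, anchor bin, partner
    bin).  The BED score column is ``-log10(q)`` capped at 1000; p and q
    travel in extra columns so every format round-trips losslessly.
    """
    if fmt not in _FORMATS:
        raise ValueError(f"unknown output format {fmt!r}; choose from {_FORMATS}")
    path = Path(path)
    res = calls.resolution
    lines: list[str] = []
    if fmt == "txt":
        lines.append(_TXT_HEADER)
        for c in calls.sorted():
            ps, pe = c.partner_interval(res)
            lines.append(
                f"{c.anchor_name}\t{c.anchor_bin}\t{c.partner_bin}\t"
                f"{calls.chromosome}\t{ps}\t{pe}\t{c.p:.6e}\t{c.q:.6e}"
            )
    elif fmt == "bed":
        lines.append("#chrom\tstart\tend\tname\tscore\tstrand\tanchor_bin\tp\tq")
        for c in calls.sorted():
            ps, pe = c.partner_interval(res)
            lines.append(
                f"{calls.chromosome}\t{ps}\t{pe}\t{c.anchor_name}\t"
                f"{_neg_log10(c.q):.6g}\t.\t{c.anchor_bin}\t{c.p:.6e}\t{c.q:.6e}"
            )
    else:
        lines.append("##gff-version 3")
        for c in calls.sorted():
            ps, pe = c.partner_interval(res)
            attrs = (
                f"anchor={c.anchor_name};anchor_bin={c.anchor_bin};"
                f"p={c.p:.6e};q={c.q:.6e}"
            )
            lines.append(
                f"{calls.chromosome}\thicontacts\tcontact\t{ps + 1}\t{pe}\t"
                f"{_neg_log10(c.q):.6g}\t.\t.\t{attrs}"
            )
    path.write_text("\n".join(lines) + "\n")


def read_calls(path: str | Path, fmt: str, resolution: int, alpha: float = 0.01) -> CallSet:
    """Parse a call file written by :func:`write_calls` (any of its formats)."""
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; choose from {_FORMATS}")
    path = Path(path)
    calls: list[Call] = []
    chromosome = ""
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if fmt == "txt":
                chromosome = f[3]
                calls.append(Call(f[0], int(f[1]), int(f[2]),
                                  p=float(f[6]), q=float(f[7]),
                                  partner_start=int(f[4]), partner_end=int(f[5])))
            elif fmt == "bed":
                chromosome = f[0]
                calls.append(Call(f[3], int(f[6]), int(f[1]) // resolution,
                                  p=float(f[7]), q=float(f[8]),
                                  partner_start=int(f[1]), partner_end=int(f[2])))
            else:
                chromosome = f[0]
                attrs = dict(kv.split("=", 1) for kv in f[8].split(";"))
                calls.append(Call(attrs["anchor"], int(attrs["anchor_bin"]),
                                  (int(f[3]) - 1) // resolution,
                                  p=float(attrs["p"]), q=float(attrs["q"]),
                                  partner_start=int(f[3]) - 1, partner_end=int(f[4])))
    return CallSet(chromosome=chromosome, resolution=resolution, calls=calls, alpha=alpha)


# ---------------------------------------------------------------------------
# liftover (UCSC chain files)
# ---------------------------------------------------------------------------

class ChainLiftover:
    """Minimal UCSC chain-file position mapper (cis use: same chromosome names)."""

    def __init__(self, path: str | Path):
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"chain file not found: {path}")
        # per target chrom: sorted block list (t_start, t_end, q_pos, q_strand, q_chrom, q_size)
        self.blocks: dict[str, list[tuple[int, int, int, str, str, int]]] = {}
        self._parse(path)

    def _parse(self, path: Path) -> None:
        with open(path) as fh:
            header = None
            t_pos = q_pos = 0
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                if line.startswith("chain"):
                    f = line.split()
                    # chain score tName tSize tStrand tStart tEnd qName qSize qStrand qStart qEnd id
                    header = {
                        "t_name": f[2], "t_size": int(f[3]), "t_strand": f[4],
                        "t_start": int(f[5]), "q_name": f[7], "q_size": int(f[8]),
                        "q_strand": f[9], "q_start": int(f[10]),
                    }
                    if header["t_strand"] != "+":
                        raise FormatError(f"{path}: target strand must be '+'")
                    t_pos, q_pos = header["t_start"], header["q_start"]
                    continue
                if header is None:
                    raise FormatError(f"{path}: alignment data before chain header")
                f = line.split()
                size = int(f[0])
                self.blocks.setdefault(header["t_name"], []).append(
                    (t_pos, t_pos + size, q_pos, header["q_strand"],
                     header["q_name"], header["q_size"])
                )
                if len(f) == 3:
                    t_pos += size + int(f[1])
                    q_pos += size + int(f[2])
                else:
                    header = None
        for chrom in self.blocks:
            self.blocks[chrom].sort()

    def map_position(self, chrom: str, pos: int) -> tuple[str, int, str] | None:
        """Map one target position; None if it falls in a gap."""
        blocks = self.blocks.get(chrom)
        if not blocks:
            return None
        idx = bisect_right(blocks, (pos, float("inf"))) - 1
        if idx < 0:
            return None
        t_start, t_end, q_pos, q_strand, q_name, q_size = blocks[idx]
        if not (t_start <= pos < t_end):
            return None
        offset = pos - t_start
        if q_strand == "+":
            return q_name, q_pos + offset, q_strand
        return q_name, q_size - (q_pos + offset) - 1, q_strand

    def map_interval(self, chrom: str, start: int, end: int) -> tuple[str, int, int] | None:
        """Map a half-open interval by its endpoints; None if either fails."""
        a = self.map_position(chrom, start)
        b = self.map_position(chrom, end - 1)
        if a is None or b is None or a[0] != b[0] or a[2] != b[2]:
            return None
        lo, hi = min(a[1], b[1]), max(a[1], b[1])
        return a[0], lo, hi + 1


def liftover_calls(calls: CallSet, chain_path: str | Path) -> CallSet:
    """Remap call partner intervals between assemblies via a chain file.

    Unmappable calls are dropped (count logged); p/q are untouched.
    """
    lo = ChainLiftover(chain_path)
    res = calls.resolution
    kept: list[Call] = []
    n_dropped = 0
    new_chrom = calls.chromosome
    for c in calls.calls:
        start, end = c.partner_interval(res)
        mapped = lo.map_interval(calls.chromosome, start, end)
        if mapped is None:
            n_dropped += 1
            continue
        new_chrom, new_start, new_end = mapped
        kept.append(Call(c.anchor_name, c.anchor_bin, new_start // res,
                         p=c.p, q=c.q, rep_p=c.rep_p, rep_q=c.rep_q,
                         significant=c.significant,
                         partner_start=new_start, partner_end=new_end))
    if n_dropped:
        logger.warning("liftover: dropped %d unmappable calls", n_dropped)
    return CallSet(chromosome=new_chrom, resolution=res, calls=kept, alpha=calls.alpha)
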