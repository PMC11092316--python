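"""Genome coordinate model: bin tiling, cytobands, chromosome arms.

All coordinates are 0-based half-open internally (the UCSC convention);
1-based inclusive coordinates appear only in exported human-readable
tables.  Only the 22 autosomes are modelled: copy-number calling from
depth of coverage alone is ambiguous on sex chromosomes, so they are
excluded at grid construction and every downstream denominator (burden,
fraction of genome altered) is autosome-only by construction.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AUTOSOMES = tuple(str(i) for i in range(1, 23))

#: Default mappability below which a bin is flagged unusable.
DEFAULT_MAPPABILITY_FLOOR = 0.5

#: Default analysis window, in bp.
DEFAULT_BIN_SIZE = 500_000


class CytobandError(ValueError):
    """Malformed cytoband input or impossible arm derivation."""


def normalize_chrom(chrom: str) -> str:
    """Strip a ``chr`` prefix; return e.g. ``"18"`` for ``"chr18"``."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def grch38_autosome_sizes() -> dict[str, int]:
    """Chromosome sizes (bp) of the GRCh38 primary-assembly autosomes."""
    path = resources.files("cnacall.data").joinpath("grch38.autosomes.chrom.sizes")
    with path.open() as fh:
        return read_chrom_sizes(fh)


def read_chrom_sizes(source) -> dict[str, int]:
    """Read a two-column ``chrom.sizes`` table, keeping autosomes only."""
    df = pd.read_csv(source, sep="\t", header=None, names=["chrom", "size"])
    sizes: dict[str, int] = {}
    for chrom, size in zip(df["chrom"], df["size"]):
        name = normalize_chrom(str(chrom))
        if name in AUTOSOMES:
            sizes[name] = int(size)
    return sizes


@dataclass(frozen=True)
class BinGrid:
    """Fixed tiling of the autosomes into non-overlapping windows.

    ``bins`` columns: chrom (str, no ``chr`` prefix), start, end (bp,
    half-open), gc, mappability (fractions), usable (bool).  Bins are
    sorted by (chrom in karyotype order, start) and tile each chromosome
    end-to-end; the final bin of a chromosome may be shorter than
    ``bin_size``.
    """

    bins: pd.DataFrame
    bin_size: int

    def __post_init__(self) -> None:
        b = self.bins
        required = {"chrom", "start", "end", "gc", "mappability", "usable"}
        missing = required - set(b.columns)
        if missing:
            raise ValueError(f"BinGrid missing columns: {sorted(missing)}")
        bad = set(b["chrom"].unique()) - set(AUTOSOMES)
        if bad:
            raise ValueError(f"non-autosomal chromosomes in grid: {sorted(bad)}")
        widths = b["end"].to_numpy() - b["start"].to_numpy()
        if (widths <= 0).any() or (widths > self.bin_size).any():
            raise ValueError("bin widths must lie in (0, bin_size]")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def widths(self) -> np.ndarray:
        return (self.bins["end"] - self.bins["start"]).to_numpy()

    @property
    def usable(self) -> np.ndarray:
        return self.bins["usable"].to_numpy(dtype=bool)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.bins["chrom"]))

    def total_usable_bases(self) -> int:
        return int(self.widths[self.usable].sum())

    def chrom_index(self) -> np.ndarray:
        """Integer chromosome id per bin (karyotype order)."""
        order = {c: i for i, c in enumerate(self.chroms)}
        return self.bins["chrom"].map(order).to_numpy()


@dataclass(frozen=True)
class CytobandMap:
    """Cytoband and chromosome-arm coordinate system.

    ``bands``: chrom, start, end, name (e.g. ``q21.33``), stain, and a
    ``label`` column in the reporting style of the field (``18q21.33``).
    ``arms``: chrom, arm (``p``/``q``), start, end, label (``18q``); the
    p arm ends where the first centromeric (``acen``) band begins and the
    q arm starts where the last acen band ends.
    """

    bands: pd.DataFrame
    arms: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.arms is None:
            object.__setattr__(self, "arms", derive_arms(self.bands))

    def band_labels(self) -> list[str]:
        return list(self.bands["label"])

    def arm_labels(self) -> list[str]:
        return list(self.arms["label"])

    def arm_of_band(self) -> dict[str, str]:
        """Map band label -> containing arm label (acen bands -> centromere side arbitrary)."""
        out: dict[str, str] = {}
        arm_rows = {(r.chrom, r.arm): r for r in self.arms.itertuples()}
        for r in self.bands.itertuples():
            arm = "p" if r.name.startswith("p") else "q"
            row = arm_rows.get((r.chrom, arm))
            out[r.label] = row.label if row is not None else f"{r.chrom}{arm}"
        return out


def derive_arms(bands: pd.DataFrame) -> pd.DataFrame:
    """Derive p/q arm intervals from acen stains, one pair per chromosome."""
    rows = []
    for chrom, grp in bands.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        acen = grp[grp["stain"] == "acen"]
        if acen.empty:
            raise CytobandError(f"chromosome {chrom} has no acen band; cannot derive arms")
        p_end = int(acen["start"].min())
        q_start = int(acen["end"].max())
        chrom_start = int(grp["start"].min())
        chrom_end = int(grp["end"].max())
        rows.append((chrom, "p", chrom_start, p_end, f"{chrom}p"))
        rows.append((chrom, "q", q_start, chrom_end, f"{chrom}q"))
    return pd.DataFrame(rows, columns=["chrom", "arm", "start", "end", "label"])


def read_cytoband_table(path: str | Path) -> CytobandMap:
    """Parse a UCSC ``cytoBand.txt(.gz)`` file into a :class:`CytobandMap`.

    Five tab-separated columns, 0-based half-open: chrom, start, end,
    band name, Giemsa stain.  Non-autosomal chromosomes are dropped with
    a warning.  Raises :class:`CytobandError` naming the offending line
    on a malformed row, and when a chromosome lacks an acen band.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    rows = []
    dropped: set[str] = set()
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise CytobandError(
                    f"{path}:{lineno}: expected 5 tab-separated columns, got {len(fields)}"
                )
            chrom_raw, start_s, end_s, name, stain = fields
            chrom = normalize_chrom(chrom_raw)
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise CytobandError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0 or end <= start:
                raise CytobandError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            if chrom not in AUTOSOMES:
                dropped.add(chrom_raw)
                continue
            rows.append((chrom, start, end, name, stain))
    if dropped:
        logger.warning("dropped non-autosomal chromosomes: %s", sorted(dropped))
    if not rows:
        raise CytobandError(f"{path}: no autosomal bands found")
    bands = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "stain"])
    bands = bands.sort_values(
        ["chrom", "start"], key=lambda s: s.map(_karyotype_key) if s.name == "chrom" else s
    ).reset_index(drop=True)
    _check_contiguous(bands, str(path))
    bands["label"] = bands["chrom"] + bands["name"]
    return CytobandMap(bands=bands)


def _karyotype_key(chrom: str) -> int:
    return int(chrom)


def _check_contiguous(bands: pd.DataFrame, source: str) -> None:
    for chrom, grp in bands.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if (starts[1:] != ends[:-1]).any():
            raise CytobandError(f"{source}: bands on chromosome {chrom} are not contiguous")


def make_bin_grid(
    chrom_sizes: dict[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    annotations: pd.DataFrame | None = None,
    mappability_floor: float = DEFAULT_MAPPABILITY_FLOOR,
) -> BinGrid:
    """Tile the autosomes into fixed windows of ``bin_size`` bp.

    ``annotations``, if given, must carry one row per produced bin in
    order, with any of ``gc``, ``mappability``, ``blacklist`` columns.
    Without annotations every bin gets gc 0.5, mappability 1.0 and is
    usable.  A bin is usable iff mappability >= ``mappability_floor``
    and it is not blacklisted.  Non-autosomal entries in ``chrom_sizes``
    are dropped with a warning.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    sizes = {}
    for chrom, size in chrom_sizes.items():
        name = normalize_chrom(chrom)
        if name not in AUTOSOMES:
            logger.warning("excluding non-autosomal chromosome %s from bin grid", chrom)
            continue
        sizes[name] = int(size)
    if not sizes:
        raise ValueError("chrom_sizes contains no autosomes")

    rows = []
    for chrom in sorted(sizes, key=_karyotype_key):
        size = sizes[chrom]
        for start in range(0, size, bin_size):
            rows.append((chrom, start, min(start + bin_size, size)))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])

    if annotations is not None:
        if len(annotations) != len(bins):
            raise ValueError(
                f"annotations rows ({len(annotations)}) != produced bins ({len(bins)})"
            )
        ann = annotations.reset_index(drop=True)
        bins["gc"] = ann["gc"].to_numpy(dtype=float) if "gc" in ann else 0.5
        bins["mappability"] = (
            ann["mappability"].to_numpy(dtype=float) if "mappability" in ann else 1.0
        )
        blacklist = (
            ann["blacklist"].to_numpy(dtype=bool)
            if "blacklist" in ann
            else np.zeros(len(bins), dtype=bool)
        )
    else:
        bins["gc"] = 0.5
        bins["mappability"] = 1.0
        blacklist = np.zeros(len(bins), dtype=bool)

    bins["usable"] = (bins["mappability"].to_numpy() >= mappability_floor) & ~blacklist
    return BinGrid(bins=bins, bin_size=bin_size)


@dataclass(frozen=True)
class RegionOverlap:
    """Bin <-> region overlap index.

    For every cytoband and every arm: the overlapping bin indices and the
    number of bases each bin contributes to the region.  ``table``
    columns: region_type (band/arm), label, chrom, bin_index, bases.
    """

    table: pd.DataFrame

    def bins_of(self, label: str) -> pd.DataFrame:
        return self.table[self.table["label"] == label]

    def region_bases(self) -> pd.Series:
        """Total binned bases assigned to each region label."""
        return self.table.groupby("label", sort=False)["bases"].sum()


def bin_region_overlap(grid: BinGrid, cyto: CytobandMap) -> RegionOverlap:
    """Intersect the bin grid with bands and arms.

    The bases a bin contributes to a region is the width of the interval
    intersection, so per-region totals equal the region width clipped to
    the binned genome: no double counting, no loss.  Raises if grid and
    map share no overlap at all (disjoint assemblies).
    """
    records: list[tuple[str, str, str, int, int]] = []
    bins = grid.bins
    by_chrom = {
        chrom: grp for chrom, grp in bins.reset_index().groupby("chrom", sort=False)
    }
    for region_type, regions in (("band", cyto.bands), ("arm", cyto.arms)):
        for r in regions.itertuples():
            grp = by_chrom.get(r.chrom)
            if grp is None:
                continue
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            ov = np.minimum(ends, r.end) - np.maximum(starts, r.start)
            hit = ov > 0
            for idx, bases in zip(grp["index"].to_numpy()[hit], ov[hit]):
                records.append((region_type, r.label, r.chrom, int(idx), int(bases)))
    if not records:
        raise ValueError("bin grid and cytoband map do not overlap; different assemblies?")
    table = pd.DataFrame(
        records, columns=["region_type", "label", "chrom", "bin_index", "bases"]
    )
    return RegionOverlap(table=table)


_BAND_RE = re.compile(r"^(\d{1,2})([pq].*)$")


def split_band_label(label: str) -> tuple[str, str]:
    """``"18q21.33"`` -> ``("18", "q21.33")``."""
    m = _BAND_RE.match(label)
    if not m:
        raise ValueError(f"not a band label: {label!r}")
    return m.group(1), m.group(2)
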