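"""TSV/JSON readers and writers for the pipeline's table contracts.

Internal coordinates are 0-based half-open throughout; the exported
SEG-like tables convert to 1-based inclusive starts, the convention of
human-readable genome-browser tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .absolute_cn import AbsoluteProfile
from .genome_model import BinGrid, normalize_chrom
from .region_calls import RegionCallSet
from .relative_cn import RelativeProfile

COUNT_COLUMNS = ["chrom", "start", "end", "count"]


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a per-bin count TSV (chrom, start, end, count)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["chrom"] = df["chrom"].astype(str).map(normalize_chrom)
    return df[COUNT_COLUMNS]


def counts_to_array(counts: pd.DataFrame, grid: BinGrid) -> np.ndarray:
    """Align a count table 1:1 with a grid, validating coordinates."""
    if len(counts) != grid.n_bins:
        raise ValueError(
            f"count table has {len(counts)} rows, grid has {grid.n_bins} bins"
        )
    same = (
        (counts["chrom"].to_numpy() == grid.bins["chrom"].to_numpy())
        & (counts["start"].to_numpy() == grid.bins["start"].to_numpy())
        & (counts["end"].to_numpy() == grid.bins["end"].to_numpy())
    )
    if not same.all():
        raise ValueError("count table bins do not match the grid")
    return counts["count"].to_numpy(dtype=float)


def grid_from_count_table(counts: pd.DataFrame) -> BinGrid:
    """Reconstruct a plain (fully usable) grid from a count table's bins."""
    bins = counts[["chrom", "start", "end"]].copy()
    bins["gc"] = 0.5
    bins["mappability"] = 1.0
    bins["usable"] = True
    bin_size = int((bins["end"] - bins["start"]).max())
    return BinGrid(bins=bins, bin_size=bin_size)


def write_relative_seg(profile: RelativeProfile, path: str | Path) -> None:
    """SEG-like TSV: sample, chrom, start, end, n_bins, seg_mean_log2, seg_mean_linear."""
    seg = profile.segments
    out = pd.DataFrame(
        {
            "sample": profile.sample_id,
            "chrom": seg["chrom"],
            "start": seg["start"] + 1,  # 1-based inclusive for export
            "end": seg["end"],
            "n_bins": seg["n_bins"],
            "seg_mean_log2": np.log2(seg["r_mean"].to_numpy() + 1e-12),
            "seg_mean_linear": seg["r_mean"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_absolute_seg(profile: AbsoluteProfile, path: str | Path) -> None:
    """Absolute SEG-like TSV with purity and fallback columns."""
    seg = profile.segments
    out = pd.DataFrame(
        {
            "sample": profile.sample_id,
            "chrom": seg["chrom"],
            "start": seg["start"] + 1,
            "end": seg["end"],
            "n_bins": seg["n_bins"],
            "r": seg["r_mean"],
            "cn_cont": seg["cn_cont"],
            "cn": seg["cn"],
            "state": seg["state"],
            "purity_used": profile.purity_used,
            "fallback_flag": profile.fit.fallback_used,
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_region_calls(calls: RegionCallSet, path: str | Path) -> None:
    """Per-sample region-call TSV (bands with focal flag, then arms)."""
    bands = calls.band_calls.assign(region_type="band")
    arms = calls.arm_calls.assign(region_type="arm", focal=False)
    out = pd.concat([bands, arms], ignore_index=True)
    out.insert(0, "sample", calls.sample_id)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_region_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_burden(callsets: dict[str, RegionCallSet], path: str | Path) -> None:
    rows = [
        (s, c.pga, c.n_cna, c.altered_bases) for s, c in callsets.items()
    ]
    pd.DataFrame(rows, columns=["sample", "pga", "n_cna", "altered_bases"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    if "sample" not in meta.columns:
        raise ValueError(f"{path}: metadata needs a 'sample' column")
    return meta
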