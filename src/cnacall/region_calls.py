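"""Cytoband/arm-level alteration calls, focality, and burden metrics.

A region (cytoband or chromosome arm) is called altered in a direction
only when *more than* 50% of its assigned bases lie in usable bins of
that state — the strict-inequality rule; exactly half is not a call.
The denominator is the region's bases assigned through usable bins, so
a region with no usable coverage (e.g. an acrocentric p arm) is never
callable rather than dividing by zero.  An altered band is *focal* when
its containing arm is not altered in the same direction; burden is
summarized as the proportion of usable genome altered (PGA) and the
number of merged same-state altered runs (CNA count).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .absolute_cn import AbsoluteProfile
from .genome_model import BinGrid, CytobandMap, RegionOverlap, bin_region_overlap

CALL_RULE_MIN_FRACTION = 0.5  # strict: fraction must exceed this

_STATE_NAME = {1: "amplification", -1: "deletion", 0: "none"}


@dataclass(frozen=True)
class RegionCallSet:
    """Per-sample region-level calls and burden.

    ``band_calls``/``arm_calls`` columns: label, chrom, region_type,
    assigned_bases, frac_amp, frac_del, state, and (bands only) focal.
    ``pga`` is altered usable bases over total usable bases; ``n_cna``
    counts maximal runs of adjacent same-state altered usable bins
    within chromosomes.
    """

    sample_id: str
    band_calls: pd.DataFrame
    arm_calls: pd.DataFrame
    pga: float
    n_cna: int
    altered_bases: int

    def band_states(self) -> pd.Series:
        return self.band_calls.set_index("label")["state"]

    def altered_bands(self, direction: str) -> set[str]:
        want = "amplification" if direction == "amp" else "deletion"
        return set(self.band_calls.loc[self.band_calls["state"] == want, "label"])


def region_state_fractions(
    grid: BinGrid,
    overlap: RegionOverlap | CytobandMap,
    bin_state: np.ndarray,
) -> pd.DataFrame:
    """Direction-specific altered-base fractions for every region.

    ``bin_state`` is per grid bin, coded -1 (deletion) / 0 / +1
    (amplification); unusable bins contribute neither numerator nor
    denominator.  Returns one row per region with assigned_bases,
    amp_bases, del_bases, frac_amp, frac_del.
    """
    if isinstance(overlap, CytobandMap):
        overlap = bin_region_overlap(grid, overlap)
    if bin_state.shape != (grid.n_bins,):
        raise ValueError("bin_state must cover every grid bin")
    tab = overlap.table
    usable = grid.usable[tab["bin_index"].to_numpy()]
    state = bin_state[tab["bin_index"].to_numpy()]
    bases = tab["bases"].to_numpy(dtype=float)
    df = pd.DataFrame(
        {
            "region_type": tab["region_type"],
            "label": tab["label"],
            "chrom": tab["chrom"],
            "assigned": np.where(usable, bases, 0.0),
            "amp": np.where(usable & (state == 1), bases, 0.0),
            "del": np.where(usable & (state == -1), bases, 0.0),
        }
    )
    agg = (
        df.groupby(["region_type", "label", "chrom"], sort=False)[["assigned", "amp", "del"]]
        .sum()
        .reset_index()
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        agg["frac_amp"] = np.where(
            agg["assigned"] > 0, agg["amp"] / agg["assigned"], 0.0
        )
        agg["frac_del"] = np.where(
            agg["assigned"] > 0, agg["del"] / agg["assigned"], 0.0
        )
    agg = agg.rename(columns={"assigned": "assigned_bases"})
    return agg


def _state_from_fractions(frac_amp: np.ndarray, frac_del: np.ndarray) -> np.ndarray:
    state = np.full(frac_amp.shape, "none", dtype=object)
    state[frac_amp > CALL_RULE_MIN_FRACTION] = "amplification"
    state[frac_del > CALL_RULE_MIN_FRACTION] = "deletion"
    return state


def _full_bin_state(absprof: AbsoluteProfile, grid: BinGrid) -> np.ndarray:
    state = np.zeros(grid.n_bins, dtype=int)
    state[absprof.bin_index] = absprof.bin_state
    return state


def call_regions(
    absprof: AbsoluteProfile,
    grid: BinGrid,
    overlap: RegionOverlap | CytobandMap,
) -> RegionCallSet:
    """Apply the >50%-of-bases rule per band and arm; compute burden."""
    bin_state = _full_bin_state(absprof, grid)
    frac = region_state_fractions(grid, overlap, bin_state)
    frac["state"] = _state_from_fractions(
        frac["frac_amp"].to_numpy(float), frac["frac_del"].to_numpy(float)
    )
    bands = frac[frac["region_type"] == "band"].drop(columns="region_type").reset_index(drop=True)
    arms = frac[frac["region_type"] == "arm"].drop(columns="region_type").reset_index(drop=True)
    pga, n_cna, altered = burden_metrics(absprof, grid)
    callset = RegionCallSet(
        sample_id=absprof.sample_id,
        band_calls=bands,
        arm_calls=arms,
        pga=pga,
        n_cna=n_cna,
        altered_bases=altered,
    )
    callset.band_calls["focal"] = classify_focal(callset)
    return callset


def classify_focal(calls: RegionCallSet) -> np.ndarray:
    """Focal flag per band: altered without a same-direction arm call.

    Depends only on band state and same-direction arm status, so it is
    idempotent.  The containing arm is read off the band label (the arm
    letter after the chromosome number).
    """
    arm_state = calls.arm_calls.set_index("label")["state"].to_dict()
    flags = np.zeros(len(calls.band_calls), dtype=bool)
    for i, row in enumerate(calls.band_calls.itertuples()):
        if row.state == "none":
            continue
        arm_letter = "p" if row.label[len(row.chrom):].startswith("p") else "q"
        flags[i] = arm_state.get(f"{row.chrom}{arm_letter}", "none") != row.state
    return flags


def burden_metrics(
    absprof: AbsoluteProfile, grid: BinGrid
) -> tuple[float, int, int]:
    """(PGA, CNA count, altered bases) from the per-bin state track.

    PGA divides altered usable bases by all usable autosomal bases.
    CNA runs merge adjacent altered bins of identical state across
    segment boundaries within a chromosome (two touching segments at
    the same integer CN are one alteration); masked bins between two
    altered usable bins do not break a run.
    """
    idx = absprof.bin_index
    state = absprof.bin_state
    widths = grid.widths[idx]
    chroms = grid.bins["chrom"].to_numpy()[idx]
    altered = int(widths[state != 0].sum())
    total = grid.total_usable_bases()
    pga = altered / total if total else 0.0
    n_cna = 0
    prev_state = 0
    prev_chrom = None
    for s, c in zip(state, chroms):
        if s != 0 and (c != prev_chrom or s != prev_state):
            n_cna += 1
        prev_state, prev_chrom = s, c
    return pga, n_cna, altered


@dataclass(frozen=True)
class SerialComparison:
    """Shared / lost / gained direction-qualified band calls between two samples."""

    shared: tuple[str, ...]
    lost: tuple[str, ...]
    gained: tuple[str, ...]


def compare_serial(a: RegionCallSet, b: RegionCallSet) -> SerialComparison:
    """Set algebra on direction-qualified band calls of a serial pair.

    ``lost`` are calls present in ``a`` only, ``gained`` in ``b`` only.
    Output ordering is deterministic (sorted).  Raises when the two
    call sets were made against different cytoband maps.
    """
    if list(a.band_calls["label"]) != list(b.band_calls["label"]):
        raise ValueError("serial samples were called on different cytoband maps")

    def qualified(calls: RegionCallSet) -> set[str]:
        return {f"{lab}:amp" for lab in calls.altered_bands("amp")} | {
            f"{lab}:del" for lab in calls.altered_bands("del")
        }

    sa, sb = qualified(a), qualified(b)
    return SerialComparison(
        shared=tuple(sorted(sa & sb)),
        lost=tuple(sorted(sa - sb)),
        gained=tuple(sorted(sb - sa)),
    )
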