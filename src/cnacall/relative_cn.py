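"""Relative copy number: normalization and segmentation of bin counts.

Raw per-bin read counts are turned into a relative copy-number profile:
unusable bins are masked, counts are converted to rates per base, an
optional GC correction divides out a smooth quadratic trend, and the
result is scaled so the width-weighted mean over usable bins equals 1.
Segmentation is recursive binary splitting on mean shifts in
log2-transformed values, with each split accepted only when a
permutation p-value falls below ``alpha`` — the same family of
changepoint procedure (CBS) that standard shallow-WGS copy-number
pipelines delegate to, implemented here directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_model import BinGrid

LOG_EPS = 1e-3  # additive guard before log2; variance stabilization scale
WINSOR_MADS = 4.0  # clamp bins beyond +/- 4 noise SDs of a running median
_DIFF_ATOL = 1e-9  # mean shifts below this are numerical noise, not signal


@dataclass(frozen=True)
class SegmentationParams:
    alpha: float = 0.01
    min_width: int = 2
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_width < 1:
            raise ValueError("min_width must be >= 1")


@dataclass(frozen=True)
class RelativeProfile:
    """Normalized, segmented relative copy-number profile of one sample.

    ``bins``: relative value r_b per usable bin, indexed by position in
    the grid.  ``segments``: one row per segment with chrom, start/end
    (bp), start_bin/end_bin (positions into ``bins``, half-open),
    n_bins, and r_mean (the plain mean of the segment's r_b).  Segments
    partition the usable bins of every chromosome, and the
    width-weighted mean of r_b is 1.
    """

    sample_id: str
    bins: pd.Series
    segments: pd.DataFrame
    params: dict = field(default_factory=dict)


def normalize_counts(
    counts: np.ndarray | pd.Series,
    grid: BinGrid,
    correct_gc: bool = False,
) -> pd.Series:
    """Counts -> relative copy number over usable bins.

    Divides by bin width, optionally removes a smooth quadratic GC trend
    (median-of-ratios against the fitted curve), and scales so the
    width-weighted mean over usable bins is exactly 1.  Raises on a
    length mismatch or an all-zero usable profile.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (grid.n_bins,):
        raise ValueError(
            f"counts length {counts.shape} does not match grid ({grid.n_bins} bins)"
        )
    usable = grid.usable
    if not np.any(counts[usable] > 0):
        raise ValueError("all usable-bin counts are zero")
    widths = grid.widths.astype(float)
    rate = counts[usable] / widths[usable]
    if correct_gc:
        gc = grid.bins["gc"].to_numpy()[usable]
        coef = np.polyfit(gc, rate, deg=2)
        fit = np.polyval(coef, gc)
        fit = np.clip(fit, np.finfo(float).tiny, None)
        ratio = rate / fit
        rate = ratio * np.median(rate) / np.median(ratio)
    w = widths[usable]
    r = rate / np.average(rate, weights=w)
    return pd.Series(r, index=np.flatnonzero(usable), name="r")


def _split_stats(x: np.ndarray, min_width: int) -> np.ndarray:
    """|t|-like statistic of a mean shift at every admissible split of x.

    Returns an array over splits i in [min_width, n - min_width]; the
    statistic compares means of x[:i] and x[i:] with a pooled variance.
    Supports a batch of profiles (2-D input, rows are profiles).
    """
    x2d = np.atleast_2d(x)
    n = x2d.shape[1]
    cs = np.cumsum(x2d, axis=1)
    cs2 = np.cumsum(x2d**2, axis=1)
    i = np.arange(min_width, n - min_width + 1)
    n_l = i.astype(float)
    n_r = n - n_l
    sum_l = cs[:, i - 1]
    sum_r = cs[:, -1][:, None] - sum_l
    ss_l = cs2[:, i - 1] - sum_l**2 / n_l
    ss_r = (cs2[:, -1][:, None] - cs2[:, i - 1]) - sum_r**2 / n_r
    pooled = (ss_l + ss_r) / max(n - 2, 1)
    denom = np.sqrt(np.clip(pooled, 0.0, None) * (1.0 / n_l + 1.0 / n_r))
    diff = np.abs(sum_l / n_l - sum_r / n_r)
    # below _DIFF_ATOL a "shift" is floating-point jitter, not a changepoint
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(diff <= _DIFF_ATOL, 0.0, diff / denom)  # d/0 -> inf (noiseless step)
    return t if x.ndim == 2 else t[0]


def _winsorize(x: np.ndarray) -> np.ndarray:
    """Clamp isolated outlier bins to a running median +/- 4 noise SDs.

    The noise scale is the MAD of first differences (robust to any
    number of true level shifts); the window-5 running median follows
    shifts, so only single-bin spikes are shrunk, never real segments.
    No-op on short or noiseless profiles.
    """
    if len(x) < 5:
        return x
    sigma = 1.4826 * np.median(np.abs(np.diff(x))) / np.sqrt(2.0)
    if sigma == 0:
        return x
    med = (
        pd.Series(x).rolling(window=5, center=True, min_periods=1).median().to_numpy()
    )
    return np.clip(x, med - WINSOR_MADS * sigma, med + WINSOR_MADS * sigma)


def _arc_widths(n: int, min_width: int) -> list[int]:
    """Log-spaced arc widths covering everything the slice can hold."""
    widths = []
    w = max(min_width, 2)
    while w <= n - min_width:
        widths.append(w)
        w = max(w + 1, int(w * 1.5))
    return widths


def _arc_stats(x2d: np.ndarray, min_width: int, width: int) -> np.ndarray:
    """Arc-vs-complement statistic for every contiguous window of ``width``.

    The circular-segmentation form of the mean-shift test: compares the
    mean inside the window with the mean of everything outside it.
    """
    n = x2d.shape[1]
    out_n = n - width
    cs = np.concatenate(
        [np.zeros((x2d.shape[0], 1)), np.cumsum(x2d, axis=1)], axis=1
    )
    cs2 = np.concatenate(
        [np.zeros((x2d.shape[0], 1)), np.cumsum(x2d**2, axis=1)], axis=1
    )
    sums = cs[:, width:] - cs[:, :-width]
    sums2 = cs2[:, width:] - cs2[:, :-width]
    total = cs[:, -1][:, None]
    total2 = cs2[:, -1][:, None]
    ss_in = sums2 - sums**2 / width
    ss_out = (total2 - sums2) - (total - sums) ** 2 / out_n
    pooled = (ss_in + ss_out) / max(n - 2, 1)
    denom = np.sqrt(np.clip(pooled, 0.0, None) * (1.0 / width + 1.0 / out_n))
    diff = np.abs(sums / width - (total - sums) / out_n)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(diff <= _DIFF_ATOL, 0.0, diff / denom)


def _row_max_stat(x2d: np.ndarray, min_width: int) -> np.ndarray:
    """Per-row max of the binary-split and windowed-arc statistics."""
    n = x2d.shape[1]
    best = _split_stats(x2d, min_width).max(axis=1)
    for w in _arc_widths(n, min_width):
        best = np.maximum(best, _arc_stats(x2d, min_width, w).max(axis=1))
    return best


def _best_candidate(x: np.ndarray, min_width: int) -> tuple[float, list[int]]:
    """Best mean-shift move on one slice: its statistic and breakpoints.

    A binary split yields one breakpoint; an interior arc yields two
    (clamped to the slice edges when the arc is terminal).
    """
    n = len(x)
    x2d = x[None, :]
    t = _split_stats(x2d, min_width)[0]
    best_stat = float(np.max(t))
    cuts = [int(np.argmax(t)) + min_width]
    for w in _arc_widths(n, min_width):
        z = _arc_stats(x2d, min_width, w)[0]
        if np.max(z) > best_stat:
            best_stat = float(np.max(z))
            i = int(np.argmax(z))
            arc = [i, i + w]
            cuts = [c for c in arc if min_width <= c <= n - min_width]
    return best_stat, cuts


def _find_breakpoints(
    x: np.ndarray,
    params: SegmentationParams,
    rng: np.random.Generator,
) -> list[int]:
    """Recursive segmentation of one chromosome; returns breakpoints.

    Each recursion finds the strongest mean-shift move (binary split or
    interior arc, the circular-segmentation statistic) and accepts it
    when its permutation p-value is below ``alpha``; permutations run
    in chunks and stop early once the p-value provably exceeds alpha.
    """
    n = len(x)
    if n < 2 * params.min_width:
        return []
    stat_obs, cuts = _best_candidate(x, params.min_width)
    if not cuts:
        return []
    if not np.isfinite(stat_obs):
        accept = True
    elif stat_obs == 0.0:
        accept = False
    else:
        B = params.n_permutations
        needed = int(np.ceil(params.alpha * (B + 1)))  # exceedances ruling out p < alpha
        exceed = 1  # the +1 of the permutation p-value
        done = 0
        accept = True
        while done < B:
            chunk = min(125, B - done)
            perms = rng.permuted(
                np.broadcast_to(x, (chunk, n)).copy(), axis=1
            )
            exceed += int(np.sum(_row_max_stat(perms, params.min_width) >= stat_obs))
            done += chunk
            if exceed > needed:
                accept = False
                break
        if accept:
            accept = exceed / (B + 1) < params.alpha
    if not accept:
        return []
    breaks: list[int] = []
    bounds = [0, *cuts, n]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        sub = _find_breakpoints(x[lo:hi], params, rng)
        breaks.extend(lo + b for b in sub)
    breaks.extend(cuts)
    return sorted(set(breaks))


def _polish_boundaries(x: np.ndarray, breaks: list[int], min_width: int) -> list[int]:
    """Least-squares re-placement of each boundary between its neighbors.

    Arc moves at log-spaced widths can land a boundary a bin or two off;
    two passes of exact single-boundary refinement fix that without
    changing the number of segments.
    """
    breaks = sorted(breaks)
    for _ in range(2):
        moved = False
        for k, b in enumerate(breaks):
            lo = breaks[k - 1] if k else 0
            hi = breaks[k + 1] if k + 1 < len(breaks) else len(x)
            seg = x[lo:hi]
            if len(seg) < 2 * min_width:
                continue
            t = _split_stats(seg, min_width)
            new_b = lo + int(np.argmax(t)) + min_width
            if new_b != b:
                breaks[k] = new_b
                moved = True
        breaks = sorted(set(breaks))
        if not moved:
            break
    return breaks


def segment_profile(
    rel: pd.Series,
    grid: BinGrid,
    params: SegmentationParams | None = None,
) -> pd.DataFrame:
    """Segment a relative profile chromosome by chromosome.

    Splitting operates on log2(r + eps) after clamping isolated outlier
    bins to a running median +/- 4 robust noise SDs (no-op on noiseless
    input).  Deterministic under ``params.seed``.  Returns the segment
    table described on :class:`RelativeProfile`.
    """
    if params is None:
        params = SegmentationParams()
    rng = np.random.default_rng(params.seed)
    chroms_per_bin = grid.bins["chrom"].to_numpy()[rel.index.to_numpy()]
    starts = grid.bins["start"].to_numpy()
    ends = grid.bins["end"].to_numpy()
    rows = []
    pos = 0
    for chrom in dict.fromkeys(chroms_per_bin):
        mask = chroms_per_bin == chrom
        idx = rel.index.to_numpy()[mask]
        r = rel.to_numpy()[mask]
        x = _winsorize(np.log2(r + LOG_EPS))
        breaks = _polish_boundaries(x, _find_breakpoints(x, params, rng), params.min_width)
        bounds = [0, *breaks, len(r)]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            rows.append(
                (
                    chrom,
                    int(starts[idx[lo]]),
                    int(ends[idx[hi - 1]]),
                    pos + lo,
                    pos + hi,
                    hi - lo,
                    float(np.mean(r[lo:hi])),
                )
            )
        pos += len(r)
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "start_bin", "end_bin", "n_bins", "r_mean"],
    )


def build_relative_profile(
    sample_id: str,
    counts: np.ndarray | pd.Series,
    grid: BinGrid,
    correct_gc: bool = False,
    params: SegmentationParams | None = None,
) -> RelativeProfile:
    """normalize_counts + segment_profile, with the parameters recorded."""
    if params is None:
        params = SegmentationParams()
    rel = normalize_counts(counts, grid, correct_gc=correct_gc)
    segments = segment_profile(rel, grid, params)
    return RelativeProfile(
        sample_id=sample_id,
        bins=rel,
        segments=segments,
        params={
            "correct_gc": correct_gc,
            "alpha": params.alpha,
            "min_width": params.min_width,
            "n_permutations": params.n_permutations,
            "seed": params.seed,
        },
    )
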