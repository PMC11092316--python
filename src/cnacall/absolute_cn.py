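"""Absolute copy number: purity fitting and integer calling.

The core of the pipeline: with tumor ploidy fixed at 2 (hyperdiploid
states are rare in follicular lymphoma), a grid of candidate purities is
scored by how close the purity-corrected copy numbers of the sample's
non-neutral segments land to integers (the "fit matrix").  The selected
purity is the best interior local minimum of that error curve; a sample
with no non-neutral segment has no local minimum and falls back to
purity 0.2 so that alterations are still callable.  Segment relative
values are then inverted through the two-component tumor/normal mixture

    r = [rho * CN_t + (1 - rho) * 2] / [rho * psi + (1 - rho) * 2]

giving continuous copy numbers, rounded to integers and classified:
CN >= 3 is an amplification, CN <= 1 a deletion, CN == 2 neutral.  An
optional second pass at fixed purity 0.1 recovers potential subclonal
alterations in serial samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .relative_cn import RelativeProfile

AMP_MIN_CN = 3
DEL_MAX_CN = 1

#: Absolute tolerance treating two fit errors as an exact tie.
_TIE_ATOL = 1e-12


@dataclass(frozen=True)
class AbsoluteConfig:
    purity_min: float = 0.2
    purity_max: float = 1.0
    purity_step: float = 0.01
    flatness_threshold: float = 0.05
    subclonal_rerun: bool = False
    subclonal_purity: float = 0.1
    cn_cap: int = 10
    ploidy: int = 2
    fallback_purity: float = 0.2

    def purity_grid(self) -> np.ndarray:
        n = int(round((self.purity_max - self.purity_min) / self.purity_step)) + 1
        return np.round(self.purity_min + self.purity_step * np.arange(n), 10)


@dataclass(frozen=True)
class FitResult:
    """Purity error curve and the selected solution.

    ``grid_purity`` is the raw arg-min over the grid's local minima;
    ``selected_purity`` additionally carries the robust continuous
    polish around it (identical for exact inputs).
    """

    purity_grid: np.ndarray
    error_curve: np.ndarray
    local_minima: tuple[float, ...]
    selected_purity: float
    fallback_used: bool
    ploidy: int = 2
    neutral_level: float = 1.0  # diploid-anchor rescale applied to r before fitting
    grid_purity: float | None = None


@dataclass(frozen=True)
class AbsoluteProfile:
    """Integer copy-number profile of one sample at a fitted purity.

    ``segments`` adds to the relative segment table: cn_cont (continuous
    absolute CN), cn (integer), state (deletion/neutral/amplification).
    ``bin_index``/``bin_cn``/``bin_state`` give the per-usable-bin view
    used by region calling (state coded -1/0/+1).
    """

    sample_id: str
    segments: pd.DataFrame
    fit: FitResult
    purity_used: float
    bin_index: np.ndarray
    bin_cn: np.ndarray
    bin_state: np.ndarray
    config: AbsoluteConfig = field(default_factory=AbsoluteConfig)
    subclonal_rerun: "AbsoluteProfile | None" = None


def relative_to_absolute(
    r: float | np.ndarray, purity: float, ploidy: int = 2
) -> float | np.ndarray:
    """Invert the tumor/normal mixture: relative value -> continuous CN.

    cn = (r * [rho*psi + 2*(1-rho)] - 2*(1-rho)) / rho, floored at 0.
    At purity 1 this is simply r * psi.
    """
    if purity <= 0:
        raise ValueError(f"purity must be positive, got {purity}")
    scale = purity * ploidy + 2.0 * (1.0 - purity)
    cn = (np.asarray(r, dtype=float) * scale - 2.0 * (1.0 - purity)) / purity
    cn = np.maximum(cn, 0.0)
    return float(cn) if np.isscalar(r) else cn


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cdf = np.cumsum(w) / w.sum()
    return float(v[int(np.searchsorted(cdf, 0.5))])


def build_fit_matrix(
    segments: pd.DataFrame,
    config: AbsoluteConfig | None = None,
) -> FitResult:
    """Score every candidate purity against the sample's alterations.

    The neutral (diploid) level is first estimated as the bin-count-
    weighted median of segment means and divided out, so the fit is
    robust to the mean-1 normalization being dragged by large
    alterations (assumes under half the genome is altered).  Candidate
    segments are those with |r - 1| above the flatness threshold after
    anchoring; the error at purity rho is

        E(rho) = sum_s n_bins(s) * (cn_cont(s, rho) - round(cn_cont))^2

    over candidates.  The solution is the interior local minimum with
    the smallest error (exact ties resolved toward higher purity); with
    no candidate segments or no local minimum the fallback purity 0.2 is
    returned with the fallback flag set.
    """
    if config is None:
        config = AbsoluteConfig()
    grid = config.purity_grid()
    if grid.size == 0:
        raise ValueError("empty purity grid")
    if segments.empty:
        raise ValueError("no segments to fit")
    r = segments["r_mean"].to_numpy(dtype=float)
    w = segments["n_bins"].to_numpy(dtype=float)
    anchor = weighted_median(r, w)
    if anchor <= 0:
        anchor = 1.0
    # refine: average the whole neutral cluster (segments within the
    # flatness band of the median) so the anchor's noise shrinks with
    # the total neutral bin count instead of one segment's length
    near = np.abs(r / anchor - 1.0) <= config.flatness_threshold
    if near.any():
        anchor = float(np.average(r[near], weights=w[near]))
    r_adj = r / anchor
    cand = np.abs(r_adj - 1.0) > config.flatness_threshold
    if not cand.any():
        return FitResult(
            purity_grid=grid,
            error_curve=np.zeros_like(grid),
            local_minima=(),
            selected_purity=config.fallback_purity,
            fallback_used=True,
            ploidy=config.ploidy,
            neutral_level=anchor,
        )
    rc, wc = r_adj[cand], w[cand]
    errors = np.empty_like(grid)
    for j, rho in enumerate(grid):
        # unfloored inversion scored against the nearest achievable
        # (non-negative) integer: a purity that pushes a deletion below
        # zero pays the full distance to CN 0 instead of fitting for free.
        scale = rho * config.ploidy + 2.0 * (1.0 - rho)
        cn = (rc * scale - 2.0 * (1.0 - rho)) / rho
        target = np.clip(_round_half_up(cn), 0.0, None)
        contrib = wc * (cn - target) ** 2
        # leave-worst-out: one mis-segmented segment (a merged event and
        # neutral stretch has no integer CN at any purity) must not drag
        # the whole curve; with >= 4 alterations drop the largest term
        if contrib.size >= 4:
            contrib = np.sort(contrib)[:-1]
        errors[j] = float(np.sum(contrib))

    interior = np.arange(1, grid.size - 1)
    is_min = (errors[interior] < errors[interior - 1]) & (
        errors[interior] < errors[interior + 1]
    )
    minima_idx = interior[is_min]
    if minima_idx.size == 0:
        return FitResult(
            purity_grid=grid,
            error_curve=errors,
            local_minima=(),
            selected_purity=config.fallback_purity,
            fallback_used=True,
            ploidy=config.ploidy,
            neutral_level=anchor,
        )
    e_min = errors[minima_idx].min()
    tied = minima_idx[np.isclose(errors[minima_idx], e_min, rtol=0.0, atol=_TIE_ATOL)]
    selected = float(grid[tied.max()])  # exact tie -> higher purity
    refined, anchor_refined = _refine_purity(r, w, selected, anchor, config)
    return FitResult(
        purity_grid=grid,
        error_curve=errors,
        local_minima=tuple(float(grid[i]) for i in minima_idx),
        selected_purity=refined,
        fallback_used=False,
        ploidy=config.ploidy,
        neutral_level=anchor_refined,
        grid_purity=selected,
    )


def _refine_purity(
    r: np.ndarray,
    w: np.ndarray,
    rho0: float,
    anchor0: float,
    config: AbsoluteConfig,
) -> tuple[float, float]:
    """Polish the grid solution by robust alternating refitting.

    Starting from the selected grid purity, alternate (a) assigning
    each segment the nearest achievable integer CN and (b) refitting
    the neutral level and purity by weighted least squares on the
    predicted relative signal a * (1 + rho * (CN - 2) / 2), with
    bisquare weights so mis-segmented segments (which fit no integer)
    lose influence instead of dragging the estimate.  Exact inputs are
    a fixed point: with zero residuals the first refit returns the
    starting solution unchanged.
    """
    rho, a = float(rho0), float(anchor0)
    prev_assign = None
    for _ in range(30):
        cn = ((r / a) * 2.0 - 2.0 * (1.0 - rho)) / rho
        assign = np.clip(_round_half_up(cn), 0.0, float(config.cn_cap))
        x = (assign - 2.0) / 2.0
        resid = r - a * (1.0 + rho * x)
        scale = 1.4826 * float(np.median(np.abs(resid)))
        if scale > 0:
            u = np.clip(resid / (4.0 * scale), -1.0, 1.0)
            rw = (1.0 - u**2) ** 2
        else:
            rw = np.ones_like(resid)
        wt = w * rw
        s0, sx = float(wt.sum()), float((wt * x).sum())
        sxx = float((wt * x * x).sum())
        sr, sxr = float((wt * r).sum()), float((wt * x * r).sum())
        det = s0 * sxx - sx * sx
        if det <= 0:
            break
        a_new = (sxx * sr - sx * sxr) / det
        b_new = (s0 * sxr - sx * sr) / det
        if a_new <= 0:
            break
        rho_new = float(np.clip(b_new / a_new, config.purity_min, config.purity_max))
        converged = (
            prev_assign is not None
            and np.array_equal(assign, prev_assign)
            and abs(rho_new - rho) < 1e-9
        )
        rho, a = rho_new, max(a_new, 1e-12)
        prev_assign = assign
        if converged:
            break
    return rho, a


def _absolute_segments(
    rel: RelativeProfile, purity: float, neutral_level: float, config: AbsoluteConfig
) -> pd.DataFrame:
    seg = rel.segments.copy()
    r_adj = seg["r_mean"].to_numpy(dtype=float) / neutral_level
    cn_cont = relative_to_absolute(r_adj, purity, config.ploidy)
    cn = np.clip(_round_half_up(cn_cont), 0, config.cn_cap).astype(int)
    state = np.where(
        cn >= AMP_MIN_CN, "amplification", np.where(cn <= DEL_MAX_CN, "deletion", "neutral")
    )
    seg["cn_cont"] = cn_cont
    seg["cn"] = cn
    seg["state"] = state
    return seg


def _per_bin(seg: pd.DataFrame, rel: RelativeProfile) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(rel.bins)
    bin_cn = np.full(n, 2, dtype=int)
    bin_state = np.zeros(n, dtype=int)
    for row in seg.itertuples():
        sl = slice(row.start_bin, row.end_bin)
        bin_cn[sl] = row.cn
        if row.state == "amplification":
            bin_state[sl] = 1
        elif row.state == "deletion":
            bin_state[sl] = -1
    return rel.bins.index.to_numpy(), bin_cn, bin_state


def call_absolute_profile(
    rel: RelativeProfile,
    config: AbsoluteConfig | None = None,
) -> AbsoluteProfile:
    """Fit purity, convert segments to integer CN, classify states.

    With ``config.subclonal_rerun`` a second profile computed at the
    fixed subclonal purity (0.1) is attached.
    """
    if config is None:
        config = AbsoluteConfig()
    fit = build_fit_matrix(rel.segments, config)
    seg = _absolute_segments(rel, fit.selected_purity, fit.neutral_level, config)
    bin_index, bin_cn, bin_state = _per_bin(seg, rel)
    sub = None
    if config.subclonal_rerun:
        sub_cfg = replace(config, subclonal_rerun=False)
        sub_fit = FitResult(
            purity_grid=np.array([config.subclonal_purity]),
            error_curve=np.array([np.nan]),
            local_minima=(),
            selected_purity=config.subclonal_purity,
            fallback_used=False,
            ploidy=config.ploidy,
            neutral_level=fit.neutral_level,
        )
        sub_seg = _absolute_segments(
            rel, config.subclonal_purity, fit.neutral_level, sub_cfg
        )
        si, sc, ss = _per_bin(sub_seg, rel)
        sub = AbsoluteProfile(
            sample_id=rel.sample_id,
            segments=sub_seg,
            fit=sub_fit,
            purity_used=config.subclonal_purity,
            bin_index=si,
            bin_cn=sc,
            bin_state=ss,
            config=sub_cfg,
        )
    return AbsoluteProfile(
        sample_id=rel.sample_id,
        segments=seg,
        fit=fit,
        purity_used=fit.selected_purity,
        bin_index=bin_index,
        bin_cn=bin_cn,
        bin_state=bin_state,
        config=config,
        subclonal_rerun=sub,
    )
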