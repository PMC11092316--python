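"""Synthetic low-coverage WGS bin counts and cohorts with known truth.

Emulates the data this pipeline consumes: per-500-kb-bin read counts from
shallow single-end sequencing of FFPE lymphoma tissue at a target yield of
ten million reads per library, a tumor-cell fraction (purity) between 0.1
and 1.0 diluting integer tumor copy numbers toward the diploid background,
and overdispersed count noise.  Every generator is deterministic under a
single global seed; sub-streams are spawned from it so fixtures are
bit-reproducible.

The cytoband map produced here is *synthetic*: band names follow the UCSC
naming ladder (and include the bands this kind of study reports, e.g.
18q21.33, 2p15, 9p21.3) but the coordinates are an invented, deterministic
layout — suitable for exercising the coordinate machinery, not for
annotating real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_model import (
    AUTOSOMES,
    BinGrid,
    CytobandMap,
    grch38_autosome_sizes,
    make_bin_grid,
)

# Band-name ladders, telomere -> centromere for p, centromere -> telomere
# for q.  Every synthetic chromosome carries the full ladder so that any
# band of interest exists on any chromosome (names are unique only within
# a chromosome, as in the real nomenclature).
_P_LADDER = [
    "p36.33", "p36.23", "p36.22", "p36.12", "p22.3", "p22.2",
    "p21.3", "p16.1", "p15", "p14", "p13", "p12",
]
_Q_LADDER = [
    "q12", "q13.13", "q14.11", "q14.2", "q14.3", "q16.1",
    "q21.1", "q21.2", "q21.33", "q22", "q23", "q23.32", "q24",
    "q25.3", "q34",
]


def scaled_autosome_sizes(scale: int = 1) -> dict[str, int]:
    """GRCh38 autosome sizes divided by ``scale`` (smaller test genomes)."""
    return {c: max(s // scale, 1) for c, s in grch38_autosome_sizes().items()}


def synthetic_cytoband_map(chrom_sizes: dict[str, int] | None = None) -> CytobandMap:
    """Deterministic synthetic cytoband map over the given chromosomes.

    Each chromosome gets a p arm covering 40% of its length and a q arm
    covering 60%, tiled by the fixed band-name ladders with equal-width
    bands per arm, separated by a pair of centromeric ``acen`` bands
    (``p11``/``q11``) each 2% of the chromosome long.
    """
    if chrom_sizes is None:
        chrom_sizes = scaled_autosome_sizes(5)
    rows = []
    for chrom in sorted(chrom_sizes, key=int):
        size = chrom_sizes[chrom]
        p_end = int(size * 0.40)
        q_start = int(size * 0.44)
        cen_mid = int(size * 0.42)
        edges = np.linspace(0, p_end, len(_P_LADDER) + 1).astype(int)
        for name, s, e in zip(_P_LADDER, edges[:-1], edges[1:]):
            rows.append((chrom, int(s), int(e), name, "gpos50"))
        rows.append((chrom, p_end, cen_mid, "p11", "acen"))
        rows.append((chrom, cen_mid, q_start, "q11", "acen"))
        edges = np.linspace(q_start, size, len(_Q_LADDER) + 1).astype(int)
        for name, s, e in zip(_Q_LADDER, edges[:-1], edges[1:]):
            rows.append((chrom, int(s), int(e), name, "gpos50"))
    bands = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "stain"])
    bands["label"] = bands["chrom"] + bands["name"]
    return CytobandMap(bands=bands)


@dataclass(frozen=True)
class TruthProfile:
    """Ground-truth copy-number state of one simulated tumor sample.

    ``events``: non-overlapping (chrom, start, end, tumor_cn) departures
    from the diploid baseline; ``purity``: tumor-cell fraction in
    [0.1, 1.0]; bins outside every event carry ``baseline_cn`` (2).
    """

    events: tuple[tuple[str, int, int, int], ...]
    purity: float
    label: str = ""
    baseline_cn: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, cn in self.events:
            if cn == self.baseline_cn:
                raise ValueError("events must depart from the baseline copy number")
            if cn < 0:
                raise ValueError("tumor copy number must be non-negative")
            if end <= start:
                raise ValueError(f"empty event interval [{start}, {end})")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs[:-1], ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping events on chromosome {chrom}")


@dataclass(frozen=True)
class NoiseModel:
    """Count-noise model for one library.

    ``reads_per_sample``: expected total read count (default ten million,
    the target sequencing yield per library).  ``dispersion``: negative-
    binomial overdispersion d, with Var = mu + d*mu^2; d = 0 degenerates
    to Poisson.  ``noiseless``: return exact expected counts (no
    sampling).  ``gc_bias_coeffs``: optional quadratic (c0, c1, c2)
    multiplicative bias in GC fraction.
    """

    reads_per_sample: int = 10_000_000
    dispersion: float = 0.02
    gc_bias_coeffs: tuple[float, float, float] | None = None
    seed: int = 0
    noiseless: bool = False

    def __post_init__(self) -> None:
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def truth_bin_cn(grid: BinGrid, truth: TruthProfile) -> np.ndarray:
    """Base-weighted mean tumor copy number per bin (float array).

    Integer-valued whenever events align with bin boundaries.  Raises if
    an event lies outside the grid's coordinates.
    """
    cn = np.full(grid.n_bins, float(truth.baseline_cn))
    starts = grid.bins["start"].to_numpy()
    ends = grid.bins["end"].to_numpy()
    chroms = grid.bins["chrom"].to_numpy()
    chrom_span = {
        c: (int(starts[chroms == c].min()), int(ends[chroms == c].max()))
        for c in grid.chroms
    }
    for chrom, ev_start, ev_end, ev_cn in truth.events:
        span = chrom_span.get(chrom)
        if span is None or ev_start < span[0] or ev_end > span[1]:
            raise ValueError(
                f"event {chrom}:{ev_start}-{ev_end} lies outside the bin grid"
            )
        on = chroms == chrom
        ov = np.minimum(ends, ev_end) - np.maximum(starts, ev_start)
        ov = np.clip(ov, 0, None)
        frac = np.where(on, ov / (ends - starts), 0.0)
        cn += frac * (ev_cn - truth.baseline_cn)
    return cn


def expected_bin_counts(
    grid: BinGrid, truth: TruthProfile, noise: NoiseModel
) -> np.ndarray:
    """Expected count per bin under the purity mixture and GC bias.

    E[count_b] is proportional to width_b * [rho*CN_t(b) + (1-rho)*2] / 2,
    times the GC bias factor, scaled so the total equals
    ``reads_per_sample``.
    """
    rho = truth.purity
    mix = (rho * truth_bin_cn(grid, truth) + (1.0 - rho) * 2.0) / 2.0
    weight = grid.widths * mix
    if noise.gc_bias_coeffs is not None:
        c0, c1, c2 = noise.gc_bias_coeffs
        gc = grid.bins["gc"].to_numpy()
        bias = c0 + c1 * gc + c2 * gc**2
        if (bias <= 0).any():
            raise ValueError("gc bias factor must stay positive over observed GC")
        weight = weight * bias
    total = weight.sum()
    if total <= 0:
        raise ValueError("degenerate truth profile: zero expected signal")
    return noise.reads_per_sample * weight / total


def simulate_sample_counts(
    grid: BinGrid,
    truth: TruthProfile,
    noise: NoiseModel,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw per-bin counts for one sample.

    Counts are negative binomial with mean from the purity mixture and
    Var = mu + d*mu^2; Poisson when d = 0; exact expectations when
    ``noise.noiseless``.  Reproducible under ``noise.seed`` (or an
    explicit ``rng``).
    """
    mu = expected_bin_counts(grid, truth, noise)
    if noise.noiseless:
        return mu
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    if noise.dispersion == 0:
        return rng.poisson(mu).astype(float)
    n = 1.0 / noise.dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p).astype(float)


def _snap_to_bins(grid: BinGrid, chrom: str, start: int, end: int) -> tuple[int, int]:
    """Covering snap: smallest bin-aligned interval containing the region.

    Guarantees a drawn event fully spans its region even when the
    region is narrower than one bin.
    """
    on = grid.bins["chrom"].to_numpy() == chrom
    starts = grid.bins["start"].to_numpy()[on]
    ends = grid.bins["end"].to_numpy()[on]
    covered = (ends > start) & (starts < end)
    if not covered.any():
        raise ValueError(f"region {chrom}:{start}-{end} lies outside the bin grid")
    return int(starts[covered].min()), int(ends[covered].max())


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a two-group cohort with known region frequencies.

    ``region_freqs`` maps (group, region label, direction) to the
    per-sample probability of that event; a region label may be a band
    (``"18q21.33"``, focal event over that band) or an arm (``"6q"``,
    arm-level event).  ``efs_hazard_ratios`` maps (region label,
    direction) to a multiplicative hazard on the exponential event-time
    baseline; censoring is uniform on (0, ``followup_max_months``).
    """

    n_per_group: dict[str, int]
    region_freqs: dict[tuple[str, str, str], float]
    purity_range: tuple[float, float] = (0.3, 0.9)
    amp_cn: int = 3
    del_cn: int = 1
    efs_baseline_hazard: float = 0.02
    efs_hazard_ratios: dict[tuple[str, str], float] = field(default_factory=dict)
    followup_max_months: float = 120.0
    fish_band_prefix: str = "1p36"
    fish_flip_prob: float = 0.0
    fish_na_prob: float = 0.0

    def __post_init__(self) -> None:
        if not self.n_per_group or any(n <= 0 for n in self.n_per_group.values()):
            raise ValueError("every group must be non-empty")
        for key, f in self.region_freqs.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"frequency out of [0,1] for {key}: {f}")


@dataclass
class SimulatedCohort:
    """Simulated samples plus their ground truth."""

    grid: BinGrid
    cyto: CytobandMap
    counts: pd.DataFrame            # bins x samples
    metadata: pd.DataFrame          # sample, patient, group, recurrence_class, fish_1p36, efs_time, efs_event
    truths: dict[str, TruthProfile]
    truth_calls: pd.DataFrame       # samples x "label:direction" ground-truth 0/1


def _region_interval(cyto: CytobandMap, label: str) -> tuple[str, int, int]:
    bands = cyto.bands
    hit = bands[bands["label"] == label]
    if len(hit):
        r = hit.iloc[0]
        return str(r["chrom"]), int(r["start"]), int(r["end"])
    hit = cyto.arms[cyto.arms["label"] == label]
    if len(hit):
        r = hit.iloc[0]
        return str(r["chrom"]), int(r["start"]), int(r["end"])
    raise KeyError(f"unknown region label: {label}")


def _paint_events(
    grid: BinGrid,
    cyto: CytobandMap,
    drawn: list[tuple[str, str]],
    amp_cn: int,
    del_cn: int,
) -> tuple[tuple[str, int, int, int], ...]:
    """Turn drawn (label, direction) events into non-overlapping intervals.

    Events are painted onto a per-bin canvas after snapping each region
    to bin boundaries; a bin already painted by an earlier event keeps
    its state (first event wins), which guarantees the non-overlap
    invariant even for adjacent or nested regions.
    """
    cn = np.full(grid.n_bins, 2, dtype=int)
    chroms = grid.bins["chrom"].to_numpy()
    starts = grid.bins["start"].to_numpy()
    ends = grid.bins["end"].to_numpy()
    for label, direction in drawn:
        chrom, r_start, r_end = _region_interval(cyto, label)
        s, e = _snap_to_bins(grid, chrom, r_start, r_end)
        sel = (chroms == chrom) & (starts >= s) & (ends <= e) & (cn == 2)
        cn[sel] = amp_cn if direction == "amp" else del_cn
    events = []
    for chrom in dict.fromkeys(chroms):
        on = np.where(chroms == chrom)[0]
        run_start = None
        run_cn = 2
        for i in on:
            if cn[i] != run_cn:
                if run_cn != 2 and run_start is not None:
                    events.append((chrom, int(starts[run_start]), int(ends[prev]), int(run_cn)))
                run_start, run_cn = i, cn[i]
            prev = i
        if run_cn != 2 and run_start is not None:
            events.append((chrom, int(starts[run_start]), int(ends[on[-1]]), int(run_cn)))
    return tuple(events)


def truth_region_calls(
    grid: BinGrid,
    cyto: CytobandMap,
    truth: TruthProfile,
    overlap=None,
) -> dict[str, int]:
    """Ground-truth band calls by the same >50%-of-bases rule the caller uses.

    Returns {"label:amp": 0/1, "label:del": 0/1} over all bands, computed
    from the truth per-bin copy number (amplified iff CN >= 3, deleted
    iff CN <= 1) restricted to usable bins.  Pass a precomputed overlap
    index to amortize the interval intersection across samples.
    """
    from .region_calls import region_state_fractions  # local import: avoid cycle

    cn = truth_bin_cn(grid, truth)
    state = np.zeros(grid.n_bins, dtype=int)
    state[cn >= 3] = 1
    state[cn <= 1] = -1
    frac = region_state_fractions(grid, overlap if overlap is not None else cyto, state)
    bands = frac[frac["region_type"] == "band"]
    out: dict[str, int] = {}
    for row in bands.itertuples():
        out[f"{row.label}:amp"] = int(row.frac_amp > 0.5)
        out[f"{row.label}:del"] = int(row.frac_del > 0.5)
    return out


def simulate_cohort(
    spec: CohortSpec,
    grid: BinGrid,
    cyto: CytobandMap,
    seed: int = 0,
    noise: NoiseModel | None = None,
    simulate_counts: bool = True,
    overlap=None,
) -> SimulatedCohort:
    """Simulate a two-group cohort with independent per-region events.

    Each sample draws every (region, direction) of its group's frequency
    table independently; purity is uniform over ``purity_range``; counts
    follow ``noise`` (default :class:`NoiseModel`); event-free survival
    times are exponential with hazard scaled by the drawn regions'
    hazard ratios, censored uniformly.  Fully reproducible under
    ``seed``.  With ``simulate_counts=False`` only truth, metadata and
    the ground-truth call matrix are generated (fast path for
    calibration studies that never read counts).
    """
    for group, label, direction in spec.region_freqs:
        _region_interval(cyto, label)  # raises on unknown label
        if direction not in ("amp", "del"):
            raise ValueError(f"direction must be amp/del, got {direction!r}")
    if noise is None:
        noise = NoiseModel()
    if overlap is None:
        from .genome_model import bin_region_overlap

        overlap = bin_region_overlap(grid, cyto)
    rng = np.random.default_rng(seed)
    band_labels = cyto.band_labels()
    counts: dict[str, np.ndarray] = {}
    meta_rows = []
    truths: dict[str, TruthProfile] = {}
    call_rows: dict[str, dict[str, int]] = {}
    for group, n in spec.n_per_group.items():
        for k in range(n):
            sample = f"{group}_{k + 1:03d}"
            drawn = [
                (label, direction)
                for (g, label, direction), f in spec.region_freqs.items()
                if g == group and rng.random() < f
            ]
            purity = rng.uniform(*spec.purity_range)
            events = _paint_events(grid, cyto, drawn, spec.amp_cn, spec.del_cn)
            truth = TruthProfile(events=events, purity=float(purity), label=sample)
            truths[sample] = truth
            if simulate_counts:
                counts[sample] = simulate_sample_counts(grid, truth, noise, rng=rng)
            tcalls = truth_region_calls(grid, cyto, truth, overlap=overlap)
            call_rows[sample] = tcalls
            hazard = spec.efs_baseline_hazard
            for (label, direction), hr in spec.efs_hazard_ratios.items():
                if tcalls.get(f"{label}:{direction}", 0):
                    hazard *= hr
            t_event = rng.exponential(1.0 / hazard)
            t_cens = rng.uniform(0.0, spec.followup_max_months)
            efs_time = min(t_event, t_cens)
            efs_event = int(t_event <= t_cens)
            fish_true = any(
                tcalls.get(f"{b}:del", 0)
                for b in band_labels
                if b.startswith(spec.fish_band_prefix)
            )
            if rng.random() < spec.fish_na_prob:
                fish = "NA"
            else:
                obs = fish_true ^ (rng.random() < spec.fish_flip_prob)
                fish = "pos" if obs else "neg"
            meta_rows.append(
                (sample, sample, group, "primary", fish, float(efs_time), efs_event, purity)
            )
    metadata = pd.DataFrame(
        meta_rows,
        columns=[
            "sample", "patient", "group", "recurrence_class",
            "fish_1p36", "efs_time", "efs_event", "true_purity",
        ],
    )
    counts_df = pd.DataFrame(counts)
    truth_calls = pd.DataFrame.from_dict(call_rows, orient="index").loc[
        metadata["sample"]
    ]
    return SimulatedCohort(
        grid=grid, cyto=cyto, counts=counts_df, metadata=metadata,
        truths=truths, truth_calls=truth_calls,
    )


def random_truth_profile(
    grid: BinGrid,
    rng: np.random.Generator,
    purity: float | None = None,
    n_events: tuple[int, int] = (4, 8),
    min_chrom_bins: int = 20,
    min_genome_fraction: float = 0.10,
    cn_choices: tuple[int, ...] = (1, 1, 1, 3, 3, 3, 4, 0),
    event_type_probs: tuple[float, float, float] = (0.35, 0.45, 0.20),
) -> TruthProfile:
    """Random truth profile with lymphoma-like event geometry.

    Each event lands on a distinct chromosome with at least
    ``min_chrom_bins`` bins and is, with ``event_type_probs``
    (whole, arm, focal): the whole chromosome, an arm-scale block (40%
    or 60% of the chromosome, anchored at a telomere — the geometry of
    arm-level gains and losses), or a focal block of 15-35% of the
    chromosome at a random position.  Profiles are redrawn until at
    least ``min_genome_fraction`` of binned bases are altered.  Copy
    numbers come from ``cn_choices`` (weighted toward single-copy
    events, as in real lymphoma genomes).
    """
    if purity is None:
        purity = float(rng.uniform(0.3, 0.9))
    chroms = grid.bins["chrom"].to_numpy()
    starts = grid.bins["start"].to_numpy()
    ends = grid.bins["end"].to_numpy()
    sizes = {c: int((chroms == c).sum()) for c in grid.chroms}
    eligible = [c for c, nb in sizes.items() if nb >= min_chrom_bins]
    total_bases = float(grid.widths.sum())
    p_whole, p_arm, _ = event_type_probs
    for _ in range(200):
        k = int(rng.integers(n_events[0], n_events[1] + 1))
        picked = rng.choice(eligible, size=min(k, len(eligible)), replace=False)
        events = []
        altered = 0.0
        for chrom in picked:
            on = np.where(chroms == chrom)[0]
            nb = len(on)
            u = rng.random()
            if u < p_whole:
                lo, hi = on[0], on[-1]
            elif u < p_whole + p_arm:
                width = max(int(round(nb * (0.4 if rng.random() < 0.5 else 0.6))), 1)
                if rng.random() < 0.5:
                    lo, hi = on[0], on[width - 1]
                else:
                    lo, hi = on[nb - width], on[-1]
            else:
                width = max(int(round(nb * rng.uniform(0.15, 0.35))), 1)
                off = int(rng.integers(0, nb - width + 1))
                lo, hi = on[off], on[off + width - 1]
            cn = int(rng.choice(cn_choices))
            events.append((chrom, int(starts[lo]), int(ends[hi]), cn))
            altered += float(ends[hi] - starts[lo])
        if altered / total_bases >= min_genome_fraction:
            return TruthProfile(events=tuple(events), purity=purity)
    raise RuntimeError("could not satisfy the altered-fraction constraint")


def lymphoma_cohort_spec(n_pcfcl: int = 20, n_nfl: int = 64) -> CohortSpec:
    """Two-group cohort spec emulating the published frequency contrasts.

    A primary-cutaneous group (n=20) and a nodal group (n=64) share the
    common follicular-lymphoma alterations (1p36/6q/19p deletions, 1q/2p/
    12q amplifications) while the nodal group is enriched for 18q21.33
    amplification and 10q23.32 deletion, and the cutaneous group for
    13q14.11 amplification — the direction and rough size of the
    published group differences.  FISH 1p36 status is simulated from the
    truth with a 10% misclassification rate and 25% of samples untested.
    """
    freqs = {
        ("pcfcl", "18q21.33", "amp"): 0.05, ("nfl", "18q21.33", "amp"): 0.3125,
        ("pcfcl", "13q14.11", "amp"): 0.15, ("nfl", "13q14.11", "amp"): 0.016,
        ("pcfcl", "10q23.32", "del"): 0.00, ("nfl", "10q23.32", "del"): 0.172,
        ("pcfcl", "2p15", "amp"): 0.32, ("nfl", "2p15", "amp"): 0.25,
        ("pcfcl", "1p36.22", "del"): 0.25, ("nfl", "1p36.22", "del"): 0.25,
        ("pcfcl", "6q16.1", "del"): 0.21, ("nfl", "6q16.1", "del"): 0.20,
        ("pcfcl", "19p13", "del"): 0.28, ("nfl", "19p13", "del"): 0.25,
        ("pcfcl", "1q", "amp"): 0.21, ("nfl", "1q", "amp"): 0.20,
        ("pcfcl", "12q13.13", "amp"): 0.25, ("nfl", "12q13.13", "amp"): 0.20,
    }
    return CohortSpec(
        n_per_group={"pcfcl": n_pcfcl, "nfl": n_nfl},
        region_freqs=freqs,
        fish_flip_prob=0.10,
        fish_na_prob=0.25,
    )


# ---------------------------------------------------------------------------
# deterministic fixture bundle

FIXTURE_PURITIES = (0.2, 0.4, 0.8, 0.2, 0.4, 0.8)


def write_fixture_bundle(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the deterministic test bundle: 6 samples + one serial pair.

    The bundle uses a 1/5-scale genome.  Samples s1..s6 span purities
    {0.2, 0.4, 0.8}; the serial pair (pair_primary, pair_recurrence)
    shares 4 of the primary's 5 amplifications, loses one and gains two
    new events, mirroring the shared/lost/gained structure of serial
    tumor biopsies.  Re-running with the same seed is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sizes = scaled_autosome_sizes(5)
    grid = make_bin_grid(sizes)
    cyto = synthetic_cytoband_map(sizes)
    rng = np.random.default_rng(seed)
    noise = NoiseModel()

    manifest: dict[str, Path] = {}
    truths: dict[str, TruthProfile] = {}
    meta_rows = []

    for i, purity in enumerate(FIXTURE_PURITIES, start=1):
        sample = f"s{i}"
        truths[sample] = random_truth_profile(
            grid, rng, purity=purity, min_chrom_bins=20,
        )
        meta_rows.append((sample, sample, "synthetic", "primary", "NA", 24.0, 0, purity))

    # arm-scale events on distinct chromosomes so the serial structure
    # (retain 4 of 5, lose 1, gain 2) survives calling at this scale
    primary_events = [("1q", "amp"), ("2p", "amp"), ("12q", "amp"),
                      ("13q", "amp"), ("18q", "amp")]
    recurrence_events = [e for e in primary_events if e != ("13q", "amp")] + [
        ("5q", "amp"), ("7q", "del"),
    ]
    truths["pair_primary"] = TruthProfile(
        events=_paint_events(grid, cyto, primary_events, 3, 1),
        purity=0.8, label="pair_primary",
    )
    truths["pair_recurrence"] = TruthProfile(
        events=_paint_events(grid, cyto, recurrence_events, 3, 1),
        purity=0.8, label="pair_recurrence",
    )
    meta_rows.append(("pair_primary", "pair", "synthetic", "primary", "NA", 32.0, 1, 0.8))
    meta_rows.append(("pair_recurrence", "pair", "synthetic", "recurrence", "NA", 32.0, 1, 0.8))

    truth_json: dict[str, dict] = {}
    for sample, truth in truths.items():
        counts = simulate_sample_counts(grid, truth, noise, rng=rng)
        table = grid.bins[["chrom", "start", "end"]].copy()
        table["count"] = counts.astype(int)
        path = outdir / f"{sample}.counts.tsv"
        table.to_csv(path, sep="\t", index=False)
        manifest[sample] = path
        truth_json[sample] = {
            "purity": truth.purity,
            "events": [list(e) for e in truth.events],
        }

    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth_json, indent=1, sort_keys=True))
    manifest["truth"] = truth_path

    meta = pd.DataFrame(
        meta_rows,
        columns=["sample", "patient", "group", "recurrence_class",
                 "fish_1p36", "efs_time", "efs_event", "true_purity"],
    )
    meta_path = outdir / "metadata.tsv"
    meta.to_csv(meta_path, sep="\t", index=False)
    manifest["metadata"] = meta_path
    return manifest
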