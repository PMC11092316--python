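"""End-to-end evaluation runs: enrichment reproduction and recovery studies.

Collects the package's headline computations in one place so the test
suite and the reproduction script exercise identical code paths:

* the two-sided Fisher exact tests on the published 2x2 cytoband
  contrasts (the printed per-group counts are inputs; the p-values are
  recomputed here),
* predictive values from the published FISH/sequencing concordance
  counts,
* purity and integer-CN recovery on seeded synthetic samples at the
  emulated sequencing depth and noise,
* the noiseless round-trip (pipeline calls vs ground truth matrix),
* the flat-profile purity fallback,
* null calibration of the enrichment screen and of segmentation.
"""

from __future__ import annotations

import numpy as np

from .absolute_cn import AbsoluteConfig, call_absolute_profile
from .cohort_stats import concordance_from_counts, fisher_exact_2x2
from .genome_model import bin_region_overlap, grch38_autosome_sizes, make_bin_grid
from .region_calls import call_regions
from .relative_cn import SegmentationParams, _find_breakpoints, build_relative_profile
from .synthetic_data import (
    CohortSpec,
    NoiseModel,
    TruthProfile,
    random_truth_profile,
    scaled_autosome_sizes,
    simulate_cohort,
    simulate_sample_counts,
    synthetic_cytoband_map,
    truth_bin_cn,
)

#: Published cytoband contrasts: (group-A positives, group-A n,
#: group-B positives, group-B n).  A is the PCFCL-side group of each
#: comparison as printed; these counts are inputs read off published
#: result tables, and the p-values are recomputed from them.
PRINTED_CONTRASTS: dict[str, tuple[int, int, int, int]] = {
    "18q21.33_amp": (1, 20, 20, 64),
    "13q14.11-q14.2_amp": (3, 20, 1, 64),
    "10q23.32_del": (0, 28, 11, 64),
    "2p15_amp": (1, 14, 4, 5),
    "2p22.3-p16.1_amp": (1, 14, 3, 5),
    "12q13.13-q14.3_amp": (6, 13, 1, 15),
    "3q23-q24_amp": (0, 16, 5, 12),
    "9p21.3_del": (0, 16, 4, 10),
    "6q16.1-q23.3_del": (1, 16, 5, 10),
    "1p36.23-p36.22_del": (1, 13, 4, 7),
}

#: Published FISH-vs-sequencing concordance counts for the 1p36 deletion.
PRINTED_CONCORDANCE = {"tp": 4, "fp": 1, "fn": 2, "tn": 13}


def fisher_contrast_pvalues() -> dict[str, float]:
    """Recompute the two-sided Fisher p for every printed contrast."""
    return {
        name: fisher_exact_2x2(*counts)[1]
        for name, counts in PRINTED_CONTRASTS.items()
    }


def concordance_predictive_values() -> dict:
    """PPV/NPV (integer percent) from the printed concordance counts."""
    return concordance_from_counts(**PRINTED_CONCORDANCE)


def purity_cn_recovery(
    n_samples: int = 100,
    seed: int = 1,
    dispersion: float = 0.02,
    purity_tolerance: float = 0.05,
) -> dict:
    """Recovery study on the full-size 500-kb GRCh38 grid.

    Per sample: purity uniform on [0.3, 0.9], at least 10% of the genome
    altered, overdispersed counts at the 10M-read target; the full
    pipeline (normalize, segment, fit, call) runs blind and is scored
    against the generating truth.
    """
    grid = make_bin_grid(grch38_autosome_sizes())
    rng = np.random.default_rng(seed)
    purity_ok = 0
    cn_correct = 0
    cn_total = 0
    for i in range(n_samples):
        truth = random_truth_profile(grid, rng)
        counts = simulate_sample_counts(
            grid, truth, NoiseModel(dispersion=dispersion), rng=rng
        )
        rel = build_relative_profile(
            f"r{i}", counts, grid, params=SegmentationParams(seed=seed * 100_003 + i)
        )
        prof = call_absolute_profile(rel)
        purity_ok += abs(prof.purity_used - truth.purity) <= purity_tolerance
        tcn = truth_bin_cn(grid, truth)[prof.bin_index]
        altered = tcn != 2
        cn_correct += int((prof.bin_cn[altered] == tcn[altered]).sum())
        cn_total += int(altered.sum())
    return {
        "n_samples": n_samples,
        "purity_within_tolerance": purity_ok / n_samples,
        "cn_accuracy_altered_bins": cn_correct / cn_total,
    }


def roundtrip_noiseless(seed: int = 1, scale: int = 10) -> dict:
    """Noiseless purity-1 cohort: pipeline calls vs ground truth, exactly.

    The cohort draws arm-level and whole-chromosome events (terminal
    steps, which a noiseless changepoint search recovers exactly) at
    realistic frequencies.  Returns the number of mismatching entries
    of the samples x bands call matrix and of the per-sample burden
    metrics (all must be 0 for a correct pipeline).
    """
    sizes = scaled_autosome_sizes(scale)
    grid = make_bin_grid(sizes)
    cyto = synthetic_cytoband_map(sizes)
    overlap = bin_region_overlap(grid, cyto)
    # one region per chromosome: two arm events on one chromosome would
    # leave a single-bin centromeric gap that no segmentation respecting
    # min_width=2 can isolate
    freqs = {}
    for arm in ("1q", "2p", "6q", "7p", "12q", "19p"):
        freqs[("g", arm, "amp")] = 0.4
    for arm in ("3p", "9p", "13q", "18q"):
        freqs[("g", arm, "del")] = 0.4
    spec = CohortSpec(
        n_per_group={"g": 8}, region_freqs=freqs, purity_range=(1.0, 1.0)
    )
    sim = simulate_cohort(
        spec, grid, cyto, seed=seed, noise=NoiseModel(noiseless=True)
    )
    call_mismatches = 0
    burden_mismatches = 0
    entries = 0
    for sample in sim.metadata["sample"]:
        truth = sim.truths[sample]
        counts = sim.counts[sample].to_numpy()
        rel = build_relative_profile(sample, counts, grid)
        prof = call_absolute_profile(rel)
        calls = call_regions(prof, grid, overlap)
        got_states = calls.band_states()
        for label in cyto.band_labels():
            got = got_states[label]
            call_mismatches += int(
                int(got == "amplification") != sim.truth_calls.loc[sample, f"{label}:amp"]
            )
            call_mismatches += int(
                int(got == "deletion") != sim.truth_calls.loc[sample, f"{label}:del"]
            )
            entries += 2
        # exact burden truth recomputed from the generating events
        tcn = truth_bin_cn(grid, truth)
        state = np.zeros(grid.n_bins, dtype=int)
        state[tcn >= 3] = 1
        state[tcn <= 1] = -1
        true_altered = int(grid.widths[(state != 0) & grid.usable].sum())
        chroms = grid.bins["chrom"].to_numpy()
        true_ncna = 0
        prev = (None, 0)
        for c, s in zip(chroms[grid.usable], state[grid.usable]):
            if s != 0 and (c != prev[0] or s != prev[1]):
                true_ncna += 1
            prev = (c, s)
        true_pga = true_altered / grid.total_usable_bases()
        burden_mismatches += int(calls.altered_bases != true_altered)
        burden_mismatches += int(calls.n_cna != true_ncna)
        burden_mismatches += int(abs(calls.pga - true_pga) > 1e-12)
    return {
        "n_samples": int(len(sim.metadata)),
        "matrix_entries": entries,
        "call_matrix_mismatches": call_mismatches,
        "burden_mismatches": burden_mismatches,
    }


def flat_profile_fallback(scale: int = 10) -> dict:
    """All-neutral noiseless sample: fallback purity 0.2, zero CNAs."""
    sizes = scaled_autosome_sizes(scale)
    grid = make_bin_grid(sizes)
    cyto = synthetic_cytoband_map(sizes)
    truth = TruthProfile(events=(), purity=0.7, label="flat")
    counts = simulate_sample_counts(grid, truth, NoiseModel(noiseless=True))
    rel = build_relative_profile("flat", counts, grid)
    prof = call_absolute_profile(rel)
    calls = call_regions(prof, grid, bin_region_overlap(grid, cyto))
    return {
        "fallback_used": bool(prof.fit.fallback_used),
        "selected_purity": float(prof.purity_used),
        "n_local_minima": len(prof.fit.local_minima),
        "n_cna": int(calls.n_cna),
    }


def null_fisher_calibration(
    n_cohorts: int = 200, seed: int = 1, n_per_group: int = 12
) -> dict:
    """Fraction of null-band Fisher tests below .05 over simulated cohorts.

    Both groups share identical region frequencies, so every rejection
    is a false positive; the exact test's discreteness makes the rate
    conservative.
    """
    sizes = scaled_autosome_sizes(10)
    grid = make_bin_grid(sizes)
    cyto = synthetic_cytoband_map(sizes)
    bands = ["18q21.33", "2p15", "9p21.3", "6q16.1", "12q13.13",
             "1p36.22", "13q14.11", "10q23.32", "3q23", "19p13"]
    freqs = {}
    for b in bands:
        for g in ("a", "b"):
            freqs[(g, b, "amp")] = 0.2
            freqs[(g, b, "del")] = 0.1
    overlap = bin_region_overlap(grid, cyto)
    n_sig = 0
    n_tests = 0
    for rep in range(n_cohorts):
        spec = CohortSpec(n_per_group={"a": n_per_group, "b": n_per_group},
                          region_freqs=freqs)
        sim = simulate_cohort(
            spec, grid, cyto, seed=seed * 1_000_003 + rep, simulate_counts=False,
            overlap=overlap,
        )
        groups = sim.metadata.set_index("sample")["group"]
        for b in bands:
            for d in ("amp", "del"):
                col = sim.truth_calls[f"{b}:{d}"]
                a_pos = int(col[groups == "a"].sum())
                b_pos = int(col[groups == "b"].sum())
                _, p = fisher_exact_2x2(a_pos, n_per_group, b_pos, n_per_group)
                n_sig += p < 0.05
                n_tests += 1
    return {"n_tests": n_tests, "fraction_significant": n_sig / n_tests}


def null_segmentation_fpr(
    n_profiles: int = 500, n_bins: int = 100, seed: int = 1, alpha: float = 0.01
) -> dict:
    """Breakpoint rate on flat noisy profiles at significance ``alpha``."""
    rng = np.random.default_rng(seed)
    params = SegmentationParams(alpha=alpha, n_permutations=1000)
    hits = 0
    for i in range(n_profiles):
        x = rng.normal(0.0, 0.05, n_bins)
        hits += bool(_find_breakpoints(x, params, np.random.default_rng(seed * 7 + i)))
    return {"n_profiles": n_profiles, "alpha": alpha, "fraction_with_breakpoint": hits / n_profiles}


def region_rule_edge_cases() -> dict:
    """Exactly-50% altered bases not called; 50% + one base called."""
    import pandas as pd

    from .absolute_cn import FitResult, AbsoluteProfile
    from .genome_model import CytobandMap

    def build(chrom_len, band_end, deleted_bins):
        grid = make_bin_grid({"1": chrom_len}, bin_size=1000)
        bands = pd.DataFrame(
            [("1", 0, 2000, "p11", "acen"), ("1", 2000, band_end, "q12", "gneg")],
            columns=["chrom", "start", "end", "name", "stain"],
        )
        bands["label"] = bands["chrom"] + bands["name"]
        cyto = CytobandMap(bands=bands)
        state = np.zeros(grid.n_bins, dtype=int)
        state[2 : 2 + deleted_bins] = -1
        fit = FitResult(
            purity_grid=np.array([1.0]), error_curve=np.array([0.0]),
            local_minima=(1.0,), selected_purity=1.0, fallback_used=False,
        )
        prof = AbsoluteProfile(
            sample_id="edge", segments=pd.DataFrame(), fit=fit, purity_used=1.0,
            bin_index=np.arange(grid.n_bins), bin_cn=np.where(state == -1, 1, 2),
            bin_state=state, config=AbsoluteConfig(),
        )
        return call_regions(prof, grid, cyto).band_states()["1q12"]

    # band of 10,000 bases, 5,000 deleted -> exactly half -> none
    at_half = build(chrom_len=12_000, band_end=12_000, deleted_bins=5)
    # band of 9,999 bases, 5,000 deleted -> one base over half -> called
    over_half = build(chrom_len=11_999, band_end=11_999, deleted_bins=5)
    return {
        "call_at_exact_half": int(at_half != "none"),
        "call_at_half_plus_one_base": int(over_half == "deletion"),
    }
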