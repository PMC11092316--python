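"""Cohort-level statistics over region-call matrices.

Per-region enrichment between two groups uses the two-sided Fisher exact
test with no multiple-testing correction, as is conventional for this
kind of exploratory CNA screen (a Benjamini-Hochberg column is emitted
as supplementary output but is not used for any headline number).
Burden metrics are compared by the two-sided Wilcoxon rank-sum test,
FISH concordance is summarized as predictive values against FISH as the
reference standard, and event-free survival is analyzed by the
product-limit (Kaplan-Meier) estimator with the log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .region_calls import RegionCallSet


@dataclass(frozen=True)
class CohortTable:
    """Sample metadata plus a samples x (band, direction) call matrix.

    ``samples`` carries one row per sample (sample, patient, group,
    recurrence_class, fish_1p36 in {pos, neg, NA}, efs_time in months,
    efs_event).  ``calls`` is indexed by sample with 0/1 columns named
    ``label:amp`` / ``label:del``.
    """

    samples: pd.DataFrame
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.samples["sample"].is_unique:
            raise ValueError("duplicate sample ids in cohort table")
        missing = set(self.samples["sample"]) - set(self.calls.index)
        if missing:
            raise ValueError(f"samples without call rows: {sorted(missing)}")

    def group_samples(self, group: str, first_sample_only: bool = False) -> list[str]:
        rows = self.samples[self.samples["group"] == group]
        if first_sample_only and "patient" in rows.columns:
            rows = rows.drop_duplicates(subset="patient", keep="first")
        return list(rows["sample"])


def build_cohort_table(
    callsets: dict[str, RegionCallSet], metadata: pd.DataFrame
) -> CohortTable:
    """Assemble the cohort matrix from per-sample region-call sets."""
    rows = {}
    for sample, cs in callsets.items():
        row = {}
        for r in cs.band_calls.itertuples():
            row[f"{r.label}:amp"] = int(r.state == "amplification")
            row[f"{r.label}:del"] = int(r.state == "deletion")
        rows[sample] = row
    calls = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    meta = metadata[metadata["sample"].isin(calls.index)].reset_index(drop=True)
    calls = calls.loc[meta["sample"]]
    return CohortTable(samples=meta, calls=calls)


def fisher_exact_2x2(a_pos: int, a_n: int, b_pos: int, b_n: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on positives-out-of-n in two groups.

    Returns (odds ratio, p).  The two-sided p sums the probabilities of
    all tables with fixed margins that are no more probable than the
    observed one (the conventional exact two-sided rule, as in R's
    fisher.test).
    """
    table = [[a_pos, a_n - a_pos], [b_pos, b_n - b_pos]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def fisher_screen(
    table: CohortTable,
    group_a: str,
    group_b: str,
    first_sample_only: bool = True,
) -> pd.DataFrame:
    """Per-(band, direction) enrichment screen between two groups.

    With ``first_sample_only`` (the default) only each patient's first
    sample enters the 2x2 tables, so serial samples do not distort the
    denominators; pass False to count every sample.  Output is sorted
    by p and carries a supplementary Benjamini-Hochberg ``q`` column.
    """
    ids_a = table.group_samples(group_a, first_sample_only)
    ids_b = table.group_samples(group_b, first_sample_only)
    if not ids_a or not ids_b:
        raise ValueError("both groups must be non-empty")
    calls_a = table.calls.loc[ids_a]
    calls_b = table.calls.loc[ids_b]
    rows = []
    for col in table.calls.columns:
        label, direction = col.rsplit(":", 1)
        a_pos = int(calls_a[col].sum())
        b_pos = int(calls_b[col].sum())
        odds, p = fisher_exact_2x2(a_pos, len(ids_a), b_pos, len(ids_b))
        rows.append((label, direction, a_pos, len(ids_a), b_pos, len(ids_b), odds, p))
    out = pd.DataFrame(
        rows,
        columns=["label", "direction", "a_pos", "a_n", "b_pos", "b_n", "odds_ratio", "p"],
    )
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p: exact for small tie-free samples.

    Exact enumeration when the pooled size is at most 20 and there are
    no ties; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 20 and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def burden_compare(
    burden: pd.DataFrame,
    table: CohortTable,
    metric: str,
    group_a: str,
    group_b: str,
    first_sample_only: bool = True,
) -> dict:
    """Median (IQR) of a burden metric per group plus the rank-sum p.

    ``burden`` is indexed by sample with the metric as a column (as
    written by the region-calling stage).
    """
    ids_a = table.group_samples(group_a, first_sample_only)
    ids_b = table.group_samples(group_b, first_sample_only)
    if not ids_a or not ids_b:
        raise ValueError("both groups must be non-empty")
    va = burden.loc[ids_a, metric].to_numpy(dtype=float)
    vb = burden.loc[ids_b, metric].to_numpy(dtype=float)

    def med_iqr(v: np.ndarray) -> tuple[float, float, float]:
        q1, q2, q3 = np.percentile(v, [25, 50, 75])
        return float(q2), float(q1), float(q3)

    med_a, q1_a, q3_a = med_iqr(va)
    med_b, q1_b, q3_b = med_iqr(vb)
    return {
        "metric": metric,
        "median_a": med_a, "iqr_a": (q1_a, q3_a), "n_a": len(va),
        "median_b": med_b, "iqr_b": (q1_b, q3_b), "n_b": len(vb),
        "p": rank_sum_test(va, vb),
    }


def concordance_from_counts(tp: int, fp: int, fn: int, tn: int) -> dict:
    """Predictive values from concordance counts; NA where undefined."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("counts must be non-negative")
    ppv = round(100 * tp / (tp + fp)) if (tp + fp) else None
    npv = round(100 * tn / (tn + fn)) if (tn + fn) else None
    return {"TP": tp, "FP": fp, "FN": fn, "TN": tn, "PPV": ppv, "NPV": npv}


def fish_concordance(table: CohortTable, lcwgs_calls: pd.Series) -> dict:
    """Concordance of sequencing-based 1p36-deletion calls against FISH.

    FISH is the reference standard: TP counts samples positive by both,
    FP positive by sequencing only.  Samples with FISH status NA are
    excluded; predictive values are integer percentages, with an
    explicit None where a predictive value's denominator is empty.
    """
    meta = table.samples.set_index("sample")
    evaluable = meta.index[meta["fish_1p36"].isin(["pos", "neg"])]
    if len(evaluable) == 0:
        raise ValueError("no samples with evaluable FISH status")
    fish = meta.loc[evaluable, "fish_1p36"] == "pos"
    seq = lcwgs_calls.reindex(evaluable).astype(bool)
    tp = int((fish & seq).sum())
    fp = int((~fish & seq).sum())
    fn = int((fish & ~seq).sum())
    tn = int((~fish & ~seq).sum())
    return concordance_from_counts(tp, fp, fn, tn)


@dataclass(frozen=True)
class EfsResult:
    """Kaplan-Meier curves per stratum plus the two-group log-rank test."""

    stratifier: str
    curves: dict[str, pd.DataFrame]   # stratum -> columns (time, survival)
    statistic: float
    p: float
    n_per_stratum: dict[str, int]


def km_curve(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Product-limit survival estimate with right censoring."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


def efs_analysis(table: CohortTable, stratifier: str) -> EfsResult:
    """Event-free survival stratified by carrying one band-direction call.

    EFS is the time from diagnosis to recurrence, antilymphoma therapy
    or death, whichever is first; here it is whatever the metadata's
    ``efs_time``/``efs_event`` encode.  The two strata (carriers vs
    non-carriers of ``stratifier``, e.g. ``"18q21.33:amp"``) are
    compared with the 1-df log-rank chi-square.
    """
    from lifelines.statistics import logrank_test

    if stratifier not in table.calls.columns:
        raise KeyError(f"unknown stratifier column: {stratifier}")
    meta = table.samples.set_index("sample")
    if (meta["efs_time"] <= 0).any():
        raise ValueError("efs_time must be positive for all samples")
    carrier = table.calls[stratifier].astype(bool)
    strata = {"carrier": carrier[carrier].index, "noncarrier": carrier[~carrier].index}
    for name, ids in strata.items():
        if len(ids) == 0:
            raise ValueError(f"stratum {name!r} has zero samples")
    t = {k: meta.loc[ids, "efs_time"].to_numpy(float) for k, ids in strata.items()}
    e = {k: meta.loc[ids, "efs_event"].to_numpy(int) for k, ids in strata.items()}
    res = logrank_test(t["carrier"], t["noncarrier"], e["carrier"], e["noncarrier"])
    curves = {k: km_curve(t[k], e[k]) for k in strata}
    return EfsResult(
        stratifier=stratifier,
        curves=curves,
        statistic=float(res.test_statistic),
        p=float(res.p_value),
        n_per_stratum={k: len(v) for k, v in strata.items()},
    )
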