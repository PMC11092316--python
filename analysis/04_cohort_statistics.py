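#!/usr/bin/env python
"""Cohort statistics on the simulated two-group cohort.

Runs the Fisher exact enrichment screen between the two groups, the
rank-sum comparison of burden metrics, FISH-vs-sequencing concordance
for the 1p36 deletion, and Kaplan-Meier/log-rank event-free survival
for the top enriched regions.  Writes the stat tables under results/.
"""

import json
from pathlib import Path

import pandas as pd

from cnacall import io as cio
from cnacall.cohort_stats import (
    CohortTable,
    build_cohort_table,
    burden_compare,
    efs_analysis,
    fish_concordance,
    fisher_screen,
)
from cnacall.region_calls import RegionCallSet

scratch = Path("scratch/cohort")
results = Path("results")

meta = cio.read_metadata(scratch / "metadata.tsv")
callsets = {}
for sample in meta["sample"]:
    df = cio.read_region_calls(scratch / "regions" / f"{sample}.regions.tsv")
    callsets[sample] = RegionCallSet(
        sample_id=sample,
        band_calls=df[df["region_type"] == "band"].reset_index(drop=True),
        arm_calls=df[df["region_type"] == "arm"].reset_index(drop=True),
        pga=float("nan"), n_cna=-1, altered_bases=-1,
    )
table = build_cohort_table(callsets, meta)

screen = fisher_screen(table, "pcfcl", "nfl")
screen.to_csv(results / "enrichment.tsv", sep="\t", index=False, float_format="%.4g")
top = screen.head(6)
print("top enriched regions (pcfcl vs nfl, Fisher exact):")
print(top.to_string(index=False))

burden = pd.read_csv(results / "burden.tsv", sep="\t", index_col="sample")
cmp_rows = []
for metric in ("pga", "n_cna"):
    out = burden_compare(burden, table, metric, "pcfcl", "nfl")
    cmp_rows.append(
        (metric, out["median_a"], *out["iqr_a"], out["median_b"], *out["iqr_b"], out["p"])
    )
    print(
        f"{metric}: pcfcl median {out['median_a']:.3g} vs nfl {out['median_b']:.3g} "
        f"(rank-sum p={out['p']:.3f})"
    )
pd.DataFrame(
    cmp_rows,
    columns=["metric", "median_pcfcl", "q1_pcfcl", "q3_pcfcl",
             "median_nfl", "q1_nfl", "q3_nfl", "p"],
).to_csv(results / "burden_compare.tsv", sep="\t", index=False, float_format="%.4g")

# 1p36 deletion concordance: sequencing call = any 1p36 band deleted
p36_cols = [c for c in table.calls.columns if c.startswith("1p36") and c.endswith(":del")]
seq_calls = table.calls[p36_cols].any(axis=1)
conc = fish_concordance(table, seq_calls)
(results / "fish_concordance.json").write_text(json.dumps(conc, indent=1))
print(
    f"FISH concordance (n={sum(conc[k] for k in 'TP FP FN TN'.split())}): "
    f"TP={conc['TP']} FP={conc['FP']} FN={conc['FN']} TN={conc['TN']} "
    f"PPV={conc['PPV']}% NPV={conc['NPV']}%"
)

efs_rows = []
for col in screen.head(5).apply(lambda r: f"{r['label']}:{r['direction']}", axis=1):
    try:
        res = efs_analysis(table, col)
    except ValueError:
        continue
    efs_rows.append((col, res.n_per_stratum["carrier"],
                     res.n_per_stratum["noncarrier"], res.statistic, res.p))
efs = pd.DataFrame(
    efs_rows, columns=["stratifier", "n_carrier", "n_noncarrier", "logrank_chi2", "p"]
)
efs.to_csv(results / "efs_logrank.tsv", sep="\t", index=False, float_format="%.4g")
print("event-free survival (log-rank) for top regions:")
print(efs.to_string(index=False))
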