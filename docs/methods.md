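# Methods

`cnacall` reimplements, end to end, the copy-number analysis used for
low-coverage whole-genome sequencing (lcWGS) of FFPE lymphoma tissue:
binned read counts are normalized to a relative copy-number profile,
segmented, converted to absolute integer copy numbers through a tumor
purity fit with ploidy fixed at 2, summarized into cytoband- and
arm-level calls, and compared across a cohort with exact tests,
rank-sum burden comparisons, FISH concordance, and Kaplan–Meier /
log-rank survival analysis.  A synthetic-data generator with known
ground truth makes every stage testable without any sequencing data.

## Signal model

A sample is a mixture of tumor cells (fraction ρ, "purity") and normal
diploid cells.  A genomic window (bin) with tumor copy number `CN_t`
contributes reads in proportion to its width times the mixture copy
number

    m(b) = [ρ·CN_t(b) + (1 − ρ)·2] / 2 ,

normalized so the genome-wide level is 1.  The relative profile `r_b`
estimates `m(b)` up to a global scale.  Inverting the mixture at a
candidate purity gives the continuous absolute copy number

    cn(r, ρ, ψ=2) = ( r·[ρψ + 2(1 − ρ)] − 2(1 − ρ) ) / ρ ,

which equals `r·ψ` at ρ = 1.  Reported `cn_cont` is floored at 0 and
integer CN is capped at 10 (`cn_cap`) as numeric hygiene on noisy
low-purity fits.  CN ≥ 3 is an amplification, CN ≤ 1 a deletion.

## Genome model

Only the 22 autosomes are modelled; depth-only copy-number calling on
sex chromosomes is ambiguous, and excluding them at grid construction
keeps every burden denominator consistent.  Bins are fixed 500-kb
windows (the final bin of a chromosome may be shorter).  Coordinates
are 0-based half-open internally; exported SEG-like tables are 1-based
inclusive.  A bin is usable when its mappability is at least 0.5
(configurable; mappability-filtered bin files in circulation do not
standardize this cutoff, so the default here is declared, not inferred)
and it is not blacklisted.  Cytobands follow the UCSC `cytoBand.txt`
dialect; arm intervals are derived from the centromeric `acen` bands.
Regions with no usable bins (e.g. acrocentric p arms) keep zero
assigned bases and are never callable, avoiding a zero denominator in
the 50% rule.

## Normalization and segmentation

Counts are divided by bin width, optionally GC-corrected by
median-of-ratios against a quadratic fit of rate on GC, and scaled so
the width-weighted mean over usable bins is 1.  Segmentation operates
on `log2(r + 1e-3)` (variance stabilization) after clamping isolated
outlier bins to a window-5 running median ± 4 robust noise SDs, where
the noise SD comes from the MAD of first differences.  A global
median-based clamp was rejected: when more than half of a chromosome
is altered the global median sits on the altered level and such a
clamp flattens the true signal.

Changepoints are found per chromosome by recursive splitting in the
circular-binary-segmentation family: at each recursion the strongest
mean-shift move is either a binary split (two-sample t over all cut
points) or an interior arc (window-vs-rest statistic over log-spaced
window widths — the circular statistic, which is what gives CBS its
power for short interstitial events).  The move is accepted when its
permutation p-value is below `alpha` (default 0.01, 1000 permutations,
early-stopped in chunks once p ≥ alpha is certain), and the procedure
recurses into the resulting pieces.  Segments are never shorter than
`min_width` (default 2 bins).  A final pass re-places each boundary by
exact least squares between its neighbors, correcting the bin-or-two
offset that log-spaced arc widths can leave.  Mean shifts below 1e-9
are treated as zero so that constant stretches cannot produce
spurious infinite statistics from floating-point jitter.  Everything
is deterministic under the segmentation seed.

On noiseless profiles, terminal (telomere-anchored or whole-arm) steps
are recovered exactly; a short noiseless interstitial plateau can
still be merged when no permuted arrangement is less likely than the
observed one — the permutation test is honest about that limit.

## Purity fit (fit matrix)

With ploidy fixed at 2 (hyperdiploid lymphomas are rare), candidate
purities 0.20–1.00 in steps of 0.01 are scored against the sample's
alterations:

1. **Diploid anchor.**  The relative profile is mean-normalized, so
   with a sizeable altered fraction the neutral level is displaced
   from 1.  The anchor is estimated as the bin-count-weighted median
   of segment means, refined to the weighted mean of the "neutral
   cluster" (segments within the flatness band of that median), and
   divided out.  This assumes under half the genome is altered, which
   holds for this disease.
2. **Candidate segments.**  Segments with |r − 1| > 0.05 after
   anchoring ("every relative alteration"); flat segments carry no
   purity information.
3. **Error curve.**  E(ρ) = Σ_s n_bins(s) · (cn_s(ρ) − t_s(ρ))² over
   candidates, where `cn_s` is the *unfloored* mixture inversion and
   `t_s` the nearest achievable (non-negative) integer.  Scoring the
   floored value instead would let every deletion fit perfectly at
   implausibly low purity (negative cn → 0 → zero residual), creating
   spurious ρ/2 solutions.  With at least four candidates the single
   largest term is dropped (leave-worst-out): a mis-segmented segment
   that mixes an event with neutral bins sits at a half-level, fits no
   integer at any purity, and lands exactly on an integer at ρ/2, so
   one such segment must not steer the curve.
4. **Selection.**  Interior local minima of E; the minimum with the
   smallest error wins, exact ties resolve to the higher purity (a
   CN {1,3} profile at ρ is algebraically identical to CN {0,4} at
   ρ/2; single-copy events are the parsimonious reading, and they
   correspond to the higher purity).  With no candidates or no local
   minimum, purity falls back to 0.2 with a flag, so alterations
   remain callable in near-flat samples.
5. **Polish.**  From the selected grid point, alternate integer-CN
   assignment with a bisquare-weighted least-squares refit of
   (anchor, purity) on all segments in relative-signal space.  Robust
   weights keep mis-segmented segments from dragging the estimate;
   exact inputs are a fixed point, so noiseless behavior is
   unchanged.  The FitResult records both the raw grid argmin and the
   polished purity.

Scoring residuals on the relative-signal scale inside E itself was
tried and rejected: it makes ρ/2 harmonics exact ties that noise then
breaks randomly.  On the copy-number scale the harmonic error is four
times the true one, which separates them reliably.

An optional second pass at fixed ρ = 0.1 (`subclonal_rerun`) recovers
potential subclonal alterations in serial samples; it replaces manual aligned visual inspection of serial bin profiles
with a deterministic re-run.

## Region calls, focality, burden

A cytoband or arm is called altered in a direction only when strictly
more than 50% of its assigned bases (bases contributed through usable
bins) lie in bins of that state; exactly half is not a call.  An
altered band is *focal* when its containing arm is not altered in the
same direction — "focal" has no formal definition in this literature,
and this is the reproducible reading of the focal-vs-arm framing.  Burden metrics:
PGA = altered usable bases / total usable autosomal bases; the CNA
count merges adjacent altered bins of identical state within a
chromosome across segment boundaries (two touching segments at the
same integer CN are one alteration), and masked bins do not interrupt
a run.  Serial samples are compared by set algebra on
direction-qualified band calls (shared / lost / gained).

## Cohort statistics

Per-(band, direction) enrichment between groups uses the conventional
exact two-sided Fisher test (probability-mass ordering, as in R's
`fisher.test`), with no multiple-testing correction — the convention such screens
report — while a Benjamini–Hochberg `q` column is emitted
as supplementary output and used for nothing else.  By default only
each patient's first sample enters the 2×2 tables, so serial samples
do not distort denominators (an `all samples` switch covers the
complementary analysis).  Burden metrics are
compared with the two-sided Wilcoxon rank-sum test, exact for pooled
n ≤ 20 without ties, otherwise the normal approximation with tie and
continuity corrections.  FISH is the reference standard for the 1p36
concordance; predictive values are integer percentages with an
explicit NA when a denominator is empty.  Event-free survival uses
the product-limit estimator and the 1-df log-rank test (lifelines).

## Synthetic data

The generator emulates this assay's data geometry: 500-kb bins over the
GRCh38 autosomes, a target yield of 10 million reads per library,
tumor purity diluting integer CN toward diploid, and
negative-binomial counts with Var = μ + d·μ² (d = 0 is Poisson;
`noiseless` returns exact expectations).  The default dispersion is
0.02 — at 500-kb bins this gives a per-bin CV of ≈ 14%, a plausibly
noisy FFPE library; published lcWGS analyses rarely characterize their
noise, so this is a declared choice.  GC bias, when requested, is a quadratic
multiplicative factor.

Random truth profiles draw 4–8 events on distinct chromosomes — 35%
whole-chromosome, 45% arm-scale telomere-anchored (40% or 60% of the
chromosome), 20% interstitial focal (15–35%) — with tumor CN from
{1, 3} three times as often as {0, 4}, matching the dominance of
single-copy gains and losses in follicular-lymphoma genomes;
profiles are redrawn until ≥ 10% of the genome is altered.  Cohorts
draw band- or arm-level events independently per region at
group-specific frequencies (no linkage between adjacent bands unless
an arm event is requested), exponential event-free survival times
with region-conditional hazard ratios and uniform censoring, and
FISH 1p36 status derived from the truth with configurable
misclassification and missingness.  All randomness derives from one
seed.

The cytoband map used in simulations is *synthetic*: the band-name
ladder includes the bands this literature reports (18q21.33, 2p15,
9p21.3, …) on every chromosome, but the coordinates are an invented
deterministic layout (p arm 40% of the chromosome, q arm 56%, 4%
centromere).  It exercises the coordinate machinery; it does not
annotate real data.  What passing tests show is therefore that the
*machinery* is correct under the declared generative model — they say
nothing about wet-lab artifacts such as fragment-length bias,
formalin-induced base damage, or real mappability structure, which
the generator does not model.

## Problem sizes and numerical choices

The purity/CN recovery study runs on the full-size 5,760-bin grid:
on strongly scaled-down genomes focal events span several-fold fewer
bins than on the real genome, which makes segmentation
artificially underpowered and induces ρ/2 aliasing that the real
geometry does not show.  Round-trip and calibration studies use
1/10-scale genomes (587 bins), where their guarantees are scale-free;
the deterministic fixture bundle uses a 1/5-scale genome so that
every chromosome keeps enough bins for decisive arm-level splits.
The noiseless round-trip draws one arm event per chromosome: two arm
events on the same chromosome would leave a single-bin centromeric
gap that no segmentation respecting `min_width = 2` can isolate.

Ties in the fit error are compared at an absolute tolerance of 1e-12;
conventional round-half-up is used for integer CN (banker's rounding
would map cn 2.5 and 3.5 both away from 3); permutation p-values are
`(1 + #{perm ≥ obs}) / (B + 1)`.

## Known limitations

* Purity is unidentifiable for near-flat genomes; the 0.2 fallback is
  a floor, not an estimate, and samples dominated by {0, 4} events
  admit a genuine ρ/2 ↔ 2ρ ambiguity that only the odd-CN prior
  resolves.
* Detection of focal events spanning ~1–2 bins at purity ≤ 0.4 is
  power-limited; cohort frequencies of such events are attenuated
  relative to truth (visible in the analysis drivers' summaries).
* No allele-specific copy number at this coverage; ploidy other than
  2 is out of scope; no liftover or non-human genomes.
* Numerical equivalence with the QDNAseq/DNAcopy stack is claimed at
  the level of behavior on synthetic data, not bit-for-bit.
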