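# Methods

This note documents the models behind `spermage`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic-data
generator does and does not emulate.

## Coordinates and formats

All internal coordinates are 0-based half-open. Conversions happen only at
format boundaries: cytosine reports are 1-based (reverse-strand CpGs are
collapsed onto the forward-strand C of the dyad and counts summed, since
CpG methylation in pooled bisulphite data is strand-symmetric), BED and
bedGraph are 0-based half-open. Zero-coverage sites are dropped at read
time because β = m/t is undefined there. Age groups are contiguous bins
1: 18–25, 2: 26–35, 3: 36–45, 4: 46–55, 5: 56–65, 6: 66+ — the open-ended
last bin starts at 66 so that every age has exactly one group.

## Synthetic study generator

Every generator is a pure function of (config, seed); independent RNG
streams are derived per layer and, for methylomes, per donor id, so a
donor's track does not change when the cohort is subset.

**Cohort.** Ages are uniform within each group's bin with group sizes
34/36/28/39/36/24 (197 donors). Each clinical parameter, DFI and rTL is a
linear age trend plus Gaussian noise: value = b₀ + b₁·age + ε. Trend
parameters (units per year) are set so group means run over clinically
plausible ranges, e.g. ejaculate volume ~4.2 ml → ~2.0 ml and FSH
~3 → ~6 U/l between the youngest and oldest groups. Clinical values are
clipped at zero. Defaults for the molecular layers:

| quantity | intercept | slope / year | noise SD | note |
|---|---|---|---|---|
| rTL blood (ratio) | 1.275 | −0.0055 | 0.08 | shortening somatic telomeres |
| rTL sperm (ratio) | 0.615 | +0.0077 | 0.08 | lengthening germline telomeres |
| DFI (%) | 3.2 | +0.38 | 10.0 | clipped to [0, 100] |

The telomere slopes are the study conditions themselves; the noise SDs are
free parameters chosen once as clinically plausible scatter (per-donor rTL
ratios vary on the order of 0.1; within-group DFI SDs are around 10
percentage points). A few donors lack rTL measurements (3 blood, 18
sperm), mirroring incomplete assay coverage (n = 194 / 179). With these
choices the cohort-level DFI–age Spearman ρ comes out near 0.5–0.6 and
roughly 80% of the oldest group exceeds the 25% DFI limit.

**Methylomes.** The CpG landscape is fixed per genome: ~100 bp mean
background spacing (two chromosomes of 50,000 CpGs by default), with
background β drawn from a bimodal mixture (80% Beta(9,1) — the highly
methylated sperm genome bulk, 15% Beta(1,19) — unmethylated islands, 5%
Beta(2,2)). Implanted DMR truths sit on locally dense CpG clusters
(20–80 bp spacing), emulating the CpG-rich regulatory elements real DMRs
fall in. Twenty truths per tissue alternate direction (slope ±0.008 β/yr
from baselines 0.15 / 0.85), giving |Δβ| ≈ 0.4 between pooled young
(18–25) and old (66+) groups; sperm and blood truth anchors interleave
along the chromosome so the two truth sets are disjoint by construction.
Counts are total ~ Poisson(30) per CpG with zeros raised to one (an
approximation to a truncated Poisson; the bias at mean 30 is negligible)
and methylated ~ Binomial(total, β). Expected β inside a truth is
clamp(baseline + slope·(age − 18), 0, 1); clamping never binds for the
default baselines within ages 18–84.

**DBS panel.** Eleven regions: six with slope ±0.006 β/yr and five
essentially flat (±0.0002). Donor-level biological scatter (SD 0.03 on β)
plus Binomial(depth = 1000) sampling gives the strong regions Spearman
p ≪ 0.001 against age in a 42-donor cohort while the flat regions stay
non-significant, so region selection recovers exactly the six real
regions. Training mirrors the study design: the 12 pool donors plus 30
random others; validation is 33 further random donors.

**Embryo trajectories.** Four stages (sperm → early/mid/late pronucleus).
Escapee trajectories decay mildly (start 0.55–0.9, total drop ≤ 0.25,
minimum ≥ 0.35); non-escapees demethylate to below 0.10. A configurable
fraction (default 10%) sits exactly on the 0.30 thresholds — a minimum of
exactly 0.30 (still an escapee, the persistence rule is ≥) or a range of
exactly 0.30 (not an escapee, the variation rule is <) — so the boundary
conventions are exercised, with floating-point guards ensuring the
constructed range never rounds below the threshold.

What the generator does **not** emulate: inter-donor background
methylation variability (the landscape is shared, so all between-pool
background differences are binomial noise), cell-composition effects in
blood, non-linear or threshold-shaped age effects, assay batch effects and
non-Gaussian clinical error structure, and read-level artefacts (bisulfite
conversion failure, mapping bias). Passing tests therefore demonstrate
correctness of the algorithms under a clean linear-trend model, not
robustness to those real-data complications.

## DMR calling

**Smoothing.** Coverage-weighted boxcar mean: smoothed β at site i is
Σm/Σt over sites within ±window/2 bp (window 1000 bp), widened to the
nearest sites when fewer than 5 fall inside. A boxcar keeps constants
invariant and makes the single-site window the identity; with pooled
coverage ~180× the extra variance reduction of a tapered kernel is not
needed.

**Run-based caller.** Candidate regions are maximal runs of consecutive
CpGs with |smoothed difference| ≥ 0.10, constant sign and inter-CpG gaps
≤ 300 bp. Reported group means are raw (unsmoothed, unweighted) means over
the run's CpGs.

**Segmentation caller.** Recursive segmentation of the raw per-CpG
difference d. The candidate segment maximizes the scan statistic
|Σd|/√L over windows of length ≥ 4 (geometric length grid, factor 1.4,
with greedy one-CpG boundary refinement; ties resolve to the shorter,
leftmost window). Normalizing by √L is deliberate: maximizing the mean
degenerates to minimum-length windows, which a signed-rank test can never
accept (the smallest two-sided exact p at n = 4 is 0.125), while
maximizing the raw sum can bridge unrelated regions across long noisy
gaps; √L is the classical scan-statistic compromise that makes a genuine
block beat both. A candidate is accepted if it has ≥ 4 CpGs, |mean d| ≥
0.10 and a two-sided Wilcoxon signed-rank p ≤ 0.05 for the per-CpG
differences; acceptance recurses into both flanks (depth ≤ 32), rejection
stops the branch. With one pooled track per group there are no biological
replicates, so significance rests on within-segment per-CpG differences —
a deliberate deviation from replicate-based t-statistics, documented here.
Under the null the maximizing segment is either long and diffuse (fails
the effect filter) or too short (fails the rank test), so recursion ends
immediately; no multiple-testing correction is applied across segments
because the consensus effect-size filter dominates the error budget.

**Consensus.** Any overlap between same-direction calls from the two
callers qualifies; the intersection is reported, with CpG count and raw
group means recomputed on it, and kept iff n_CpGs ≥ 4 and |Δβ| ≥ 0.30.
The 30% filter is applied to raw means on the consensus interval (whether
the original analysis used smoothed or raw means is not stated; raw means
are the assumption-free choice). Overlapping same-direction consensus
intervals are merged. Swapping the group labels flips every sign and
direction but leaves intervals unchanged.

## Escapee classification

Escapee iff min β ≥ 0.30 and range < 0.30 across stages up to and
including the late pronucleus. "Above 30%" is implemented as ≥ and
"below 30%" as <; the source statements are ambiguous at equality, and
these conventions are fixed for determinism and asserted by dedicated
boundary tests. "Variation" is the range (max − min) — the stricter,
assumption-free reading — with the standard deviation available behind
`variation_stat="sd"`. Stages after the late pronucleus are ignored;
missing stage values raise rather than being imputed.

## Sperm age predictor

Age is regressed on methylation (the predictor outputs age) by plain OLS
with intercept; no regularization, because k = 6 regions ≪ n = 42 donors
and a singular design signals a real data problem (constant or duplicated
regions), which raises an error naming the offenders. Region selection:
Spearman p < 0.001, at most the six smallest p, ties broken by |ρ| then
region id. LOOCV refits on each leave-one-out subset explicitly; in-sample
and LOOCV errors are reported separately (they answer different
questions, and LOOCV MAE ≥ in-sample MAE in expectation). Predictions are
not clamped to the study age range so extrapolation stays visible.

## Ageing statistics

Spearman ρ uses average ranks on ties. p-values use the t approximation
t = ρ√((n−2)/(1−ρ²)) with n−2 degrees of freedom; for n ≤ 8 the exact
permutation distribution is enumerated instead (8! = 40,320 permutations —
the largest n where full enumeration is practical; beyond that the t
approximation is accurate for the sample sizes this package targets).
Partial rank correlation residualizes value- and age-ranks on
confounder-ranks by least squares and correlates the residuals, with
n − 2 − (number of confounders) degrees of freedom. rTL uses the
2^−ΔΔCt single-copy-gene method with an explicit calibrator. DFI
pathology uses strict > at the 25% threshold ("values above" the maximum
normal value). Group summaries report sample SD (n−1); single-donor
groups report SD as NaN.

A note on the generator-calibration check: each (parameter, group) cell
mean is itself a Gaussian draw, so over ~100 cells a few are expected just
outside two pooled standard errors; the calibration test asserts ≥ 90% of
cells within 2 SE and all within 4 SE, which is the statistically correct
reading of "group means follow the configured trend".

## Repeat enrichment

The null relocates each DMR uniformly within its own chromosome, length
preserved, independently per permutation — per-chromosome counts and
lengths are controlled, mirroring standard interval-enrichment practice.
p-values use the add-one rule (1 + #{perm ≥ obs})/(n_perm + 1), so p is
never zero and the test is valid (super-uniform under the null). The
calibration experiment in the test suite uses 300 DMRs over a half-covered
toy chromosome: with few DMRs the integer overlap count makes the
permutation p lumpy and conservative, and the empirical type-I error would
sit below its nominal level for discreteness reasons alone; 300 regions
make the statistic near-continuous so the nominal 5% level is actually
attained. Neighbour-gene assignment is by TSS distance ≤ 1 Mb on either
side (distance 0 inside the DMR); gene-set enrichment itself is exported,
not computed.

## Problem sizes and determinism

Default simulations use 2 × 50,000 CpGs, 12 pooled donors per tissue at
30× coverage, 42 + 33 DBS donors at depth 1000, and 10,000 enrichment
permutations — sizes at which the full pipeline runs in seconds on one
core while leaving every statistical property measurable. All RNG streams
derive from a single seed via `numpy` `SeedSequence`; identical inputs
give byte-identical outputs.

## Known limitations

* The two DMR callers are transparent stand-ins, not reimplementations of
  published callers; only the consensus filter is meant to be exact.
* One pooled track per group means no replicate-level inference; the
  segmentation test treats CpGs, not donors, as units.
* The linear age model is assumed everywhere (generation and fitting);
  real methylation–age relationships can saturate.
* Permutation enrichment ignores repeat-class clustering beyond what the
  per-chromosome relocation preserves.
* The package is assembly-agnostic: coordinates are whatever the inputs
  use, and no liftover is provided.
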