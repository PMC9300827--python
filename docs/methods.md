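# Methods

This note records the models, parameter choices and numerical decisions
behind `dexdyn`, and what the synthetic-data validation does and does
not demonstrate.

## Read model and demultiplexing

Reads follow a package-defined dialect, `dna_key + barcode_a + UMI +
barcode_b`: the per-sample DNA key is a primer tag (default 8 nt), each
dextramer is identified by a *pair* of 25-mer barcodes, and the random
UMI stretch (default 10 nt) between them supports clonal reduction.
Real screens of this kind use combined A/B oligos with random
stretches; since no read structure is published for the emulated assay,
the layout here is an explicit convention (documented in
`docs/formats.md`), not a reproduction.

Matching uses Hamming distance only (no indels): substitution errors
dominate in the targeted amplicons, and near-exact matching keeps
assignment unambiguous. Defaults: 0 mismatches for keys, 1 per 25-mer
barcode. Keys and barcodes are validated to be pairwise separated by
more than twice the tolerance, so a match is never ambiguous; reads
failing any component are tallied by reason, and assigned + discarded =
scanned always holds. The clonal layer counts distinct (sample, pMHC,
UMI) triples.

All downstream statistics use the clonally reduced layer (configurable
via `layer=`): clonal reduction removes PCR duplication, which would
otherwise inflate the count model's confidence.

## Enrichment statistics

**Normalization.** Between-sample scaling uses the trimmed mean of
M-values with the standard recipe: reference = sample whose depth-scaled
75th count percentile is closest to the cohort mean; M and A computed on
barcodes nonzero in both sample and reference; 30 % two-sided trim on M,
5 % on A; inverse delta-method-variance weights; factors rescaled to
geometric mean 1. The implementation is cross-checked in the test suite
against edgeR's `calcNormFactors` (to 1e-8) and against a literal
step-by-step transcription of the formula.

**Fold change.** log2FC = log2((c+q)/Ñ_s) − log2((m̄+q)/Ñ_in), with q a
pseudocount (default 1) preventing −∞ at zero counts, m̄ the mean input
count and Ñ the TMM-effective library sizes.

**p-values.** No test is prescribed for the emulated assay, so the
choice is a declared design decision behind a strategy interface. The
default is the conditional exact binomial: for barcode count k in the
sample and pooled count m across the input replicates, k | (k+m) ~
Binomial(k+m, Ñ_s/(Ñ_s+Ñ_in,total)) under the null. Conditioning matters:
testing k against the input *mean* as if it were known ignores the
sampling noise of a 3-replicate mean and inflates the type-I error by a
factor ~4/3 in variance under Poisson sampling; the conditional form is
the classical exact test for comparing Poisson counts with offsets and
is calibrated (verified empirically: raw p < 0.05 rate ≈ 4.9 % on null
simulations at full screen size). Two-sided p-values use the central
method (2 × min tail, capped at 1), which vectorises and coincides with
the minimum-likelihood method to numerical noise at the count sizes of
this assay. BH adjustment is applied across the full library within
each sample.

**Calling thresholds** (all three must hold): read fraction ≥ 0.1 % of
the sample's clonal reads (guards against calls from a handful of
reads), BH-adjusted p < 0.01, log2FC > 1.5. All are configurable; the
log2FC cutoff in particular is exposed because printed thresholds of
the form "1,5" are typographically ambiguous.

**Frequencies.** The FACS multimer-positive CD8+ percentage of a sample
is split across its responding barcodes proportionally to clonal reads,
so per-sample estimated frequencies sum to the gate percentage exactly.

## Dynamics scores

Appearing = FU\BL, disappearing = BL\FU, stable = BL∩FU on the response
sets; score A is the triple of counts, score B = |appearing| −
|disappearing|; the cohort is dichotomized at score B > 0 vs ≤ 0, with
empty-at-both-timepoints patients scored 0 and grouped
"decreased/balanced" by definition. Patients with more than one BL or
FU sample are rejected rather than silently merged. The delta matrix
encodes presence changes as −1/0/+1 per (patient, population); its row
sums equal score B identically. The elastic net consumes this ±1
encoding by default ("changes in numbers of populations"); an encoding
based on frequency changes can be substituted by passing a different
matrix, since the selection operates on any patients × features frame.

## Survival modelling

Cox fits maximize the Efron partial likelihood (lifelines, Newton
precision 1e-9) — Efron because months-resolution data tie heavily and
it is the default of mainstream survival software. Monotone likelihood
/ separation is *flagged*, not hidden: a fit is marked non-estimable if
the solver fails, emits a convergence warning, or any |β| exceeds 10
(hazard-ratio factor > e¹⁰, beyond any plausible effect here).

The elastic-net path uses scikit-survival's glmnet port. For each α in
{0.1, …, 1.0}: λ is chosen on the 80 % training split by 10-fold
cross-validated partial-likelihood deviance in the Verweij–Van
Houwelingen form (deviance of the full training set at the fold model's
coefficients minus the in-fold deviance), with the **1-SE rule** as
default (`cv_rule="min"` available): the most parsimonious λ within one
standard error of the CV minimum. The 1-SE rule is the standard choice
when the goal is feature *selection* rather than prediction; with
`"min"`, cross-validation on pure-noise matrices frequently retains
spurious features. The split is stratified by event status (folds
cannot outnumber the smaller event stratum; the fold count is reduced
with a log message on small cohorts). α is then chosen by Harrell's
concordance on the held-out 20 % — "prediction accuracy" is undefined
for a Cox model, and the c-index is its standard surrogate — with ties
broken toward fewer selected features, then larger α.

The univariate screen operationalizes "potentially unreliable" as: the
candidate's univariate Cox fit is non-estimable, or its Wald and
log-rank significance verdicts at 0.05 disagree. Survivors enter one
joint multivariate Cox model (no stepwise selection); populations with
multivariate Wald p < 0.05 are the "independent" set feeding the
combinatorial model, which flags patients losing ≥ 1 such population
and compares flagged vs unflagged OS by KM, log-rank and univariate
Cox. If all patients share a flag, the KM curve is still produced and
the log-rank is reported as not applicable.

## Synthetic cohorts

The generator emulates the structure of the study: 36 patients with
paired BL/FU samples, a 167-entry library, an input triplicate,
two-to-one male:female and roughly half mono- vs combination-therapy
covariates, and a planted hazard ratio of 0.24 for the increased
dynamics group (the reported OS effect). Defaults that no source
states are set once to field-realistic values:

* `depth` = 5×10⁵ clonal reads/sample (no depths are reported for the
  assay; amplicon screens on Ion Torrent chips are in this range), with
  lognormal per-sample variation (`depth_cv` = 0.3).
* `background_dispersion` = 0.3: barcode abundances in a pooled
  library are uneven; a gamma composition weight per barcode with this
  dispersion gives marginally negative-binomial counts of the
  overdispersion seen in amplicon data. The weight is *shared* between
  patient samples and the input triplicate — as the physical library
  composition is — so the enrichment contrast is skew-free and the
  count noise per cell is Poisson. Independent per-cell NB noise would
  instead represent biological replicate variability, which the input
  triplicate (a technical replicate of one pool) cannot estimate.
* dynamics: Poisson(5) baseline populations, persistence 0.7,
  Poisson(3) appearing — giving cohorts that straddle the score-B
  dichotomy with occasional strongly-increased patients.
* survival: exponential by default (baseline hazard 0.04/month for the
  decreased/balanced group ⇒ ~76 % one-year survival for a mixed
  cohort), Weibull optional; censoring exponential and independent of
  group, tuned to ~20 % censoring.
* PCR duplication: Poisson(0.5 × clonal) duplicate reads per cell, so
  clonal ≤ total holds by construction and FASTQ round trips are exact.

`simulate_informative_cohort` plants hazard signal directly in a few
delta-matrix columns (log hazard `log(0.15)` per unit of their sum,
±1 prevalence 0.3 vs 0.05 for noise columns) for validating the
selection cascade in isolation.

**What passing tests show — and don't.** Recovery results (sensitivity
≥ 95 % at 8-fold enrichment, cascade recovery of planted populations,
direction recovery of the planted hazard) demonstrate internal
consistency of the pipeline under its own generative model. Real
screens add PCR amplification bias, sequencer-specific indel errors,
batch effects between staining runs, and biological correlation between
populations — none of which the generator emulates (by design; see
Non-goals in the module docstrings). Clinical effect sizes from the
emulated study (hazard ratios 0.24/0.3/40.96) are used only as planted
parameters, not as reproduced estimates: the underlying patient-level
data are not deposited.

## Problem sizes used in validation

Acceptance-style checks run at the study's structural scale (167
barcodes, 36 patients, 75 samples) over 10 seeds for calibration and
recovery; survival direction uses 150 patients × 50 seeds; the cascade
uses 150 patients × 117 populations × 20 seeds each for planted and
null cohorts. Unit and property tests use 2–8-patient cohorts with
small libraries so the whole suite, including two FASTQ round trips
and an edgeR cross-check, completes in a few minutes.

## Known limitations

* TMM reference selection follows the f75 rule; explicitly passing a
  degenerate reference column is not protected beyond the all-zero
  check.
* The conditional binomial treats the TMM-effective sizes as fixed;
  uncertainty in the normalization factors themselves is ignored (as in
  all standard count-normalization pipelines).
* The elastic-net c-index on a 20 % test split of a 36-patient cohort
  (7 patients) is extremely noisy; the cascade is validated at n=150,
  and at true study size its α choice should be treated as heuristic.
* `combinatorial_model` conditions on populations selected from the
  same cohort; its p-values are therefore optimistic (as in the
  emulated analysis) and are validated only for direction/recovery on
  independent synthetic truth.
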