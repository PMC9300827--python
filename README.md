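# dexdyn

Analysis of DNA-barcoded pMHC-dextramer T-cell screens in longitudinal
immunotherapy cohorts — from raw barcode sequencing reads to per-patient
melanoma-associated-epitope (MAE)-specific CD8+ T-cell response calls,
dynamics scores and survival modelling.

## The problem

Large dextramer libraries (here: up to 167 HLA-A\*02:01-restricted
melanoma epitopes, each reagent tagged with two unique 25-mer DNA
barcodes) allow an entire antigen-specific CD8+ T-cell repertoire to be
read out by sequencing the barcodes of multimer-bound, FACS-sorted
cells. Comparing a patient's baseline (BL) sample with an on-therapy
follow-up (FU) sample reveals which epitope-specific populations
*appear*, *disappear* or remain *stable* under checkpoint blockade —
and whether those dynamics carry prognostic information.

`dexdyn` implements the complete computational chain for such a screen:

1. **Demultiplexing and counting** (`barcode_io`) — reads of layout
   `DNA-key + barcode-A + UMI + barcode-B` are assigned to a (sample,
   pMHC) pair by matching the sample key and *both* 25-mer barcodes
   (Hamming distance, default tolerance 1 per barcode); total reads and
   clonally reduced (distinct-UMI) reads are tallied per cell.
2. **Enrichment and response calling** (`enrichment`) — for each
   barcode *b* in patient sample *s*,

   log2FC(b, s) = log2((c_bs + q) / Ñ_s) − log2((m̄_b + q) / Ñ_in)

   where c is the clonal count, m̄ the mean count across the triplicate
   library-input samples, q a pseudocount and Ñ the TMM-effective
   library size (trimmed mean of M-values, the edgeR recipe). A
   conditional exact binomial test compares each count against the
   pooled input, with Benjamini–Hochberg adjustment across the library
   within each sample. A barcode is a **T-cell response** when its read
   fraction ≥ 0.1 %, adjusted p < 0.01 and log2FC > 1.5. Population
   frequencies (% of CD8+ T cells) are obtained by splitting the FACS
   multimer-positive percentage across responding barcodes by read share.
3. **Dynamics scores** (`tmaes`) — per patient, the response sets at BL
   and FU yield the triple *score A* = (n_appearing, n_disappearing,
   n_stable) and the scalar *score B* = n_appearing − n_disappearing;
   score B > 0 defines the "increased" signature group, ≤ 0 the
   "decreased/balanced" group.
4. **Survival modelling** (`survival`) — Kaplan–Meier curves and
   log-rank tests of the score-B groups; an elastic-net-penalized Cox
   model (penalty λ·[α‖β‖₁ + (1−α)‖β‖₂²/2], α grid on [0.1, 1], λ by
   10-fold cross-validation on an 80 % training split, α by concordance
   on the held-out 20 %) that selects prognostic population dynamics
   from the patients × populations matrix of presence changes (−1/0/+1);
   a univariate Wald/log-rank screen; a joint multivariate Cox model;
   and a combinatorial model flagging patients who lose at least one of
   the independently prognostic populations.
5. **Group statistics** (`cohort_stats`) — Wilcoxon matched-pairs,
   Mann–Whitney U, Spearman correlation and a confounder association
   matrix for immune-phenotype tables.
6. **Synthetic cohorts** (`synthlib`) — because the original patient
   data are not public, a generator plants known response sets,
   dynamics groups and group-linked survival times (negative-binomial
   barcode counts, Poisson sequencing noise, exponential or Weibull
   hazards), so that every stage can be validated against ground truth.

## Worked example

Simulate a 12-patient cohort with a 60-epitope library and run the whole
pipeline:

```bash
dexdyn all --out demo --seed 7
```

or equivalently in Python:

```python
from dexdyn.cli import run_pipeline
from dexdyn.synthlib import SimParams

run_pipeline("demo", ["simulate", "call", "score", "survive", "report"],
             params=SimParams(n_patients=12, library_size=60, depth=1e5, seed=7))
```

`demo/summary.json` then contains (numbers printed by the run above):

* 12 patients, 8 with a dominantly increased signature (score B > 0) —
  e.g. patient P01 had 5 appearing, 2 disappearing and 3 stable
  populations, so score A = (5, 2, 3) and score B = +3;
* the score-B dichotomy vs overall survival: log-rank χ² = 3.70
  (p = 0.054), Cox hazard ratio 0.22 for the increased group — the
  planted protective effect (hazard ratio 0.24) recovered in direction
  and magnitude despite only 12 patients;
* the elastic-net cascade selected no populations — correct, since this
  small demo plants its hazard on the score-B group, not on individual
  populations (see `synthlib.simulate_informative_cohort` for cohorts
  with population-level signal).

Intermediate artifacts (`counts.tsv`, `enrichment.tsv`, `responses.tsv`,
`dynamics.tsv`, `delta.tsv`, KM tables) are plain TSV/CSV/JSON; schemas
are documented in `docs/formats.md`, the scientific choices in
`docs/methods.md`.

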