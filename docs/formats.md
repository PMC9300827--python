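# File formats

All artifacts are plain text (TSV/CSV/JSON/FASTQ, optionally gzip).

## Synthetic read layout (FASTQ)

Each read is the concatenation

    dna_key (key_length nt) + barcode_a (25 nt) + UMI (umi_length nt) + barcode_b (25 nt)

with constant quality. `emit_fastq` writes one pooled file; `.gz`
suffix selects gzip. This layout is a package convention (see
docs/methods.md).

## Library TSV (`library.tsv`)

Columns: `pmhc_id`, `antigen_name`, `peptide`, `epitope_label`
(= antigen name + space + first 3 peptide letters), `barcode_a`,
`barcode_b`, `hla`. `pmhc_id` and the barcode pair are unique; barcodes
are 25-mers over ACGT.

## Sample sheet CSV (`samples.csv`)

Columns: `sample_id`, `patient_id` (`input` for library-input rows),
`timepoint` (`BL`/`FU`/`INPUT`), `dna_key` (unique per sample),
`multimer_pos_pct` (FACS multimer-positive % of CD8+ T cells; empty for
INPUT rows). Every non-input patient has exactly one BL and one FU row;
INPUT rows form the triplicate.

## Count matrix TSV (`counts.tsv`)

First column `pmhc_id`; then, per sample, a `<sample>_total` and a
`<sample>_clonal` column. All entries are non-negative integers with
`clonal <= total` elementwise. `write_counts`/`read_counts` are
mutually inverse on valid matrices.

## Clinical CSV (`clinical.csv`)

`patient_id`, `os_time`, `os_event`, `pfs_time`, `pfs_event` (times in
months, events 0/1), plus covariates (`age`, `sex`, `therapy`,
`ldh_elevated`) and, for synthetic cohorts, the planted `group`.

## Enrichment TSV (`enrichment.tsv`)

One row per (barcode, patient sample): `pmhc_id`, `sample_id`,
`patient_id`, `timepoint`, `count` (clonal), `read_fraction`, `log2fc`,
`p`, `p_adj`, `is_response`.

## Responses TSV (`responses.tsv`)

`sample_id`, `pmhc_id` — one row per called response.

## Frequencies TSV (`frequencies.tsv`, `frequency_sums.tsv`)

Per responding barcode: `est_freq` (% of CD8+ T cells); per sample:
`sum_est_freq` (sums to `multimer_pos_pct` when any response is called).

## Dynamics TSV (`dynamics.tsv`)

`patient_id`, `n_appearing`, `n_disappearing`, `n_stable`, `score_b`,
`group` (`increased` / `decreased_balanced`).

## Delta matrix TSV (`delta.tsv`)

Row index `patient_id`, one column per `pmhc_id`, entries in
{−1, 0, +1} (disappeared / unchanged / appeared). Row sums equal
`score_b`.

## Discard report JSON (`*.discards.json`)

`reads_scanned`, `reads_assigned`, `reads_discarded` and a `discards`
map from reason (`no_key_match`, `no_barcode_a_match`,
`no_barcode_b_match`, `barcode_pair_mismatch`, `too_short`) to count.

## Run outputs

`survival_results.json` (per-model HRs, CIs, p-values, selection
results), `km_*.tsv` (time / survival / at-risk tables),
`summary.json` (per-patient scores plus survival results),
`manifest.json` (package version, seed, config hash, stage artifacts),
`truth.json` (synthetic ground truth for recovery scoring).
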