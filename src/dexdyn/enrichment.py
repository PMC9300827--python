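"""Barcode enrichment vs the input triplicate and T-cell response calling.

For each patient sample, barcode counts (clonally reduced by default) are
compared against the mean of the triplicate library-input samples after
trimmed-mean-of-M-values (TMM) normalization.  A barcode is called a
T-cell response when it clears three thresholds simultaneously: a minimum
read-count fraction within its sample (default 0.1%, guarding against
calls driven by a handful of reads), a Benjamini-Hochberg adjusted
p-value below 0.01, and a log2 fold-change over the input above 1.5.

The p-value strategy is pluggable; the default conditions on the sum of
the sample count and the pooled input counts, under which the count is
binomial with a success probability fixed by the TMM-effective library
sizes — the classical exact test for comparing Poisson-sampled counts,
and calibrated even though the input mean is itself estimated from only
three replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .barcode_io import CountMatrix
from .errors import ConfigurationError, DegenerateSampleError, DexdynWarning, InvalidParameterError
from .synthlib import SampleSheet


@dataclass(frozen=True)
class Thresholds:
    """Response-calling cutoffs.

    min_fraction : minimum within-sample read-count fraction (default 0.1%).
    max_p_adj : BH-adjusted p-value cutoff (default 0.01).
    min_log2fc : log2 fold-change over the input that must be exceeded
        (default 1.5; configurable).
    """

    min_fraction: float = 0.001
    max_p_adj: float = 0.01
    min_log2fc: float = 1.5

    def __post_init__(self) -> None:
        if not 0 < self.min_fraction < 1:
            raise InvalidParameterError("min_fraction must be in (0, 1)")
        if not 0 < self.max_p_adj < 1:
            raise InvalidParameterError("max_p_adj must be in (0, 1)")


# ---------------------------------------------------------------------------
# TMM normalization


def tmm_factors(
    counts: CountMatrix | np.ndarray,
    reference_sample: str | int | None = None,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    layer: str = "clonal",
) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors, one per sample.

    Follows the standard TMM recipe: log-ratios (M) and average log
    abundances (A) of each sample against a reference column are computed
    on barcodes with nonzero counts in both, the top/bottom ``trim_m`` by
    M and ``trim_a`` by A are trimmed, and the factor is 2**(weighted
    mean M) with inverse asymptotic-binomial-variance weights.  Factors
    are rescaled to geometric mean 1.

    Raises
    ------
    DegenerateSampleError
        If any sample has an all-zero count column.
    """
    if isinstance(counts, CountMatrix):
        mat = getattr(counts, layer).astype(float)
        sample_ids = counts.sample_ids
    else:
        mat = np.asarray(counts, dtype=float)
        sample_ids = list(range(mat.shape[1]))
    if mat.shape[1] < 2:
        raise InvalidParameterError("TMM needs at least 2 samples")
    libsize = mat.sum(axis=0)
    if (libsize == 0).any():
        bad = [sample_ids[j] for j in np.nonzero(libsize == 0)[0]]
        raise DegenerateSampleError(f"all-zero count column(s): {bad}")

    if reference_sample is None:
        # reference: sample whose 75th count percentile (depth-scaled) is
        # closest to the mean across samples
        f75 = np.array(
            [np.quantile(mat[:, j], 0.75) / libsize[j] for j in range(mat.shape[1])]
        )
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
    elif isinstance(reference_sample, str):
        ref = sample_ids.index(reference_sample)
    else:
        ref = int(reference_sample)

    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        factors[j] = _tmm_pair(
            mat[:, j], mat[:, ref], libsize[j], libsize[ref], trim_m, trim_a
        )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    both = (obs > 0) & (ref > 0)
    if not both.any():
        return 1.0
    o, r = obs[both], ref[both]
    p_o, p_r = o / n_obs, r / n_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    # delta-method variance of M, used as inverse weight
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    fin = np.isfinite(m) & np.isfinite(a)
    m, a, v = m[fin], a[fin], v[fin]
    n = m.size
    if n == 0:
        return 1.0
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or np.sum(1.0 / v[keep]) == 0:
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


# ---------------------------------------------------------------------------
# p-value strategies


def conditional_binomial_p(
    k: np.ndarray, m: np.ndarray, size_s: float, size_input: float
) -> np.ndarray:
    """Two-sided (central) binomial p for sample counts vs pooled input.

    Conditions on n = k + m: under the null of equal normalized
    abundance, k ~ Binomial(n, size_s / (size_s + size_input)).
    """
    k = np.asarray(k, dtype=np.int64)
    m = np.asarray(m, dtype=np.int64)
    n = k + m
    p0 = size_s / (size_s + size_input)
    lo = stats.binom.cdf(k, n, p0)
    hi = stats.binom.sf(k - 1, n, p0)
    p = np.minimum(1.0, 2.0 * np.minimum(lo, hi))
    return np.where(n == 0, 1.0, p)


# ---------------------------------------------------------------------------
# enrichment


def enrich(
    counts: CountMatrix,
    sheet: SampleSheet,
    pseudocount: float = 1.0,
    layer: str = "clonal",
    p_value: Callable[..., np.ndarray] = conditional_binomial_p,
) -> pd.DataFrame:
    """Per-(barcode, patient-sample) enrichment statistics vs the input.

    Returns a tidy frame with columns pmhc_id, sample_id, patient_id,
    timepoint, count, read_fraction, log2fc, p, p_adj.  log2fc is
    log2((c + q)/N_s') − log2((mean input + q)/N_input') with N' the
    TMM-effective library size and q the pseudocount; p comes from the
    configured strategy and is BH-adjusted across the library within each
    sample.
    """
    input_ids = [r.sample_id for r in sheet.input_rows]
    if not input_ids:
        raise ConfigurationError("sample sheet contains no INPUT samples")
    if len(input_ids) < 3:
        warnings.warn(
            f"only {len(input_ids)} input replicate(s); proceeding",
            DexdynWarning,
            stacklevel=2,
        )
    missing = [r.sample_id for r in sheet.rows if r.sample_id not in counts.sample_ids]
    if missing:
        raise ConfigurationError(f"sheet samples missing from counts: {missing}")

    mat = getattr(counts, layer).astype(float)
    order = [counts.sample_ids.index(r.sample_id) for r in sheet.rows]
    mat = mat[:, order]
    sample_ids = [r.sample_id for r in sheet.rows]
    factors = tmm_factors(mat)
    libsize = mat.sum(axis=0)
    eff_size = libsize * factors
    j_input = [sample_ids.index(s) for s in input_ids]
    input_mean = mat[:, j_input].mean(axis=1)
    input_pooled = mat[:, j_input].sum(axis=1)
    eff_input_mean = float(eff_size[j_input].mean())
    eff_input_total = float(eff_size[j_input].sum())

    frames = []
    q = pseudocount
    for r in sheet.patient_rows:
        j = sample_ids.index(r.sample_id)
        c = mat[:, j]
        log2fc = np.log2((c + q) / eff_size[j]) - np.log2(
            (input_mean + q) / eff_input_mean
        )
        p = p_value(c, input_pooled, eff_size[j], eff_input_total)
        p_adj = multipletests(p, method="fdr_bh")[1]
        frac = c / c.sum() if c.sum() > 0 else np.zeros_like(c)
        frames.append(
            pd.DataFrame(
                {
                    "pmhc_id": counts.pmhc_ids,
                    "sample_id": r.sample_id,
                    "patient_id": r.patient_id,
                    "timepoint": r.timepoint,
                    "count": c.astype(np.int64),
                    "read_fraction": frac,
                    "log2fc": log2fc,
                    "p": p,
                    "p_adj": p_adj,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def call_responses(
    records: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> set[tuple[str, str]]:
    """(sample_id, pmhc_id) pairs clearing all three response thresholds."""
    mask = (
        (records["read_fraction"] >= thresholds.min_fraction)
        & (records["p_adj"] < thresholds.max_p_adj)
        & (records["log2fc"] > thresholds.min_log2fc)
    )
    return set(
        zip(records.loc[mask, "sample_id"], records.loc[mask, "pmhc_id"])
    )


def annotate_responses(
    records: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Copy of ``records`` with a boolean ``is_response`` column added."""
    responses = call_responses(records, thresholds)
    out = records.copy()
    out["is_response"] = [
        (s, p) in responses for s, p in zip(out["sample_id"], out["pmhc_id"])
    ]
    return out


def estimate_frequencies(
    records: pd.DataFrame,
    responses: set[tuple[str, str]],
    sheet: SampleSheet,
) -> pd.DataFrame:
    """Estimated % of CD8+ T cells per responding population.

    Splits each sample's FACS multimer-positive CD8+ percentage across its
    responding barcodes proportionally to their clonal read counts, so the
    per-sample sum of estimates equals the gate percentage exactly.
    """
    rows = []
    for r in sheet.patient_rows:
        if r.multimer_pos_pct is None:
            continue
        sub = records[records["sample_id"] == r.sample_id]
        mask = np.fromiter(
            ((r.sample_id, pm) in responses for pm in sub["pmhc_id"]),
            dtype=bool,
            count=len(sub),
        )
        sub = sub[mask]
        tot = sub["count"].sum()
        for _, rec in sub.iterrows():
            share = rec["count"] / tot if tot > 0 else 0.0
            rows.append(
                {
                    "pmhc_id": rec["pmhc_id"],
                    "sample_id": r.sample_id,
                    "patient_id": r.patient_id,
                    "timepoint": r.timepoint,
                    "est_freq": share * r.multimer_pos_pct,
                }
            )
    return pd.DataFrame(
        rows, columns=["pmhc_id", "sample_id", "patient_id", "timepoint", "est_freq"]
    )


def sum_frequencies(freqs: pd.DataFrame, sheet: SampleSheet) -> pd.DataFrame:
    """Per-sample pooled estimated frequency (0 for samples with no calls)."""
    sums = freqs.groupby("sample_id")["est_freq"].sum() if len(freqs) else pd.Series(dtype=float)
    rows = [
        {
            "sample_id": r.sample_id,
            "patient_id": r.patient_id,
            "timepoint": r.timepoint,
            "sum_est_freq": float(sums.get(r.sample_id, 0.0)),
        }
        for r in sheet.patient_rows
    ]
    return pd.DataFrame(rows)
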