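"""Group-comparison statistics for immune phenotypes and a confounder matrix.

Paired BL/FU changes use the Wilcoxon matched-pairs signed-rank test,
between-group comparisons the Mann-Whitney U test, and continuous
associations Spearman rank correlation — all two-sided, with exact small-
sample distributions where the data allow.  No multiple-testing
correction is applied by default (raw p-values are reported; a BH option
exists).  The confounder matrix screens clinical covariates against each
other and against survival with a test chosen by the column types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DexdynWarning, InvalidParameterError


def paired_change_test(bl: Sequence[float], fu: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon matched-pairs signed-rank test of FU vs BL.

    Zero differences are dropped (Wilcoxon's rule); the exact null
    distribution is used for small tie-free samples and the tie-corrected
    normal approximation otherwise.  If every difference is zero the test
    is vacuous: returns (0.0, 1.0) with a warning.
    """
    bl = np.asarray(bl, dtype=float)
    fu = np.asarray(fu, dtype=float)
    if bl.shape != fu.shape or bl.size == 0:
        raise InvalidParameterError("paired vectors must be nonempty and equal length")
    diffs = fu - bl
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; p = 1", DexdynWarning, stacklevel=2)
        return 0.0, 1.0
    res = stats.wilcoxon(fu, bl, zero_method="wilcox", method="auto")
    return float(res.statistic), float(res.pvalue)


def group_compare(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidParameterError("both groups must be nonempty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (midranks for ties), two-sided p.

    Raises InvalidParameterError for n < 3 or a constant vector (the
    correlation is undefined there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.shape != y.shape:
        raise InvalidParameterError("need paired vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise InvalidParameterError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# phenotype table comparisons


@dataclass
class PhenotypeComparison:
    marker: str
    group: str
    test: str
    n: int
    statistic: float
    p: float


def phenotype_dynamics_tests(
    phenotypes: pd.DataFrame,
    groups: Mapping[str, str],
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Within-group paired BL→FU tests for every marker.

    ``phenotypes`` is tidy with columns patient_id, marker, bl, fu
    (percentages in [0, 100]); ``groups`` maps patient_id to its dynamics
    group.  Returns one row per (marker, group) with the Wilcoxon paired
    statistic and raw p (optionally BH-adjusted across rows — off by
    default, matching the convention of reporting raw phenotype p-values).
    """
    rows: list[PhenotypeComparison] = []
    df = phenotypes.copy()
    df["group"] = df["patient_id"].map(groups)
    for (marker, group), sub in df.groupby(["marker", "group"]):
        if len(sub) == 0:
            continue
        stat, p = paired_change_test(sub["bl"].to_numpy(), sub["fu"].to_numpy())
        rows.append(
            PhenotypeComparison(marker, group, "wilcoxon_paired", len(sub), stat, p)
        )
    out = pd.DataFrame([r.__dict__ for r in rows])
    if bh_correct and len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# confounder association matrix


def confounder_matrix(
    clinical: pd.DataFrame,
    column_types: Mapping[str, str],
    survival_cols: Mapping[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Symmetric matrix of pairwise association p-values between covariates.

    ``column_types`` maps column → "categorical" | "continuous".
    ``survival_cols`` optionally maps a pseudo-column name (e.g. "OS") to
    its (time, event) columns.  Tests by type pair: categorical ×
    categorical → Fisher exact (chi-square beyond 2×2); categorical ×
    continuous → Kruskal-Wallis; continuous × continuous → Spearman;
    vs survival → univariate Cox Wald p for continuous, log-rank for
    categorical.  Columns with a single level are flagged (NaN row/column)
    rather than tested; the diagonal is left blank (NaN).
    """
    names = list(column_types) + list(survival_cols or {})
    mat = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    single_level = {
        c for c, t in column_types.items()
        if clinical[c].nunique() <= 1
    }
    if single_level:
        warnings.warn(
            f"column(s) with a single level are not testable: {sorted(single_level)}",
            DexdynWarning,
            stacklevel=2,
        )
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            p = _pair_p(clinical, a, b, column_types, survival_cols or {}, single_level)
            mat.loc[a, b] = p
            mat.loc[b, a] = p
    return mat


def _pair_p(
    df: pd.DataFrame,
    a: str,
    b: str,
    types: Mapping[str, str],
    surv: Mapping[str, tuple[str, str]],
    single_level: set[str],
) -> float:
    if a in single_level or b in single_level:
        return np.nan
    a_surv, b_surv = a in surv, b in surv
    if a_surv and b_surv:
        return np.nan  # OS-vs-PFS association is not a confounding check
    if a_surv or b_surv:
        s, other = (a, b) if a_surv else (b, a)
        time_col, event_col = surv[s]
        times = df[time_col].to_numpy(dtype=float)
        events = df[event_col].to_numpy(dtype=int)
        if types[other] == "continuous":
            from .survival import cox_fit

            x = pd.DataFrame({other: pd.to_numeric(df[other])})
            fit = cox_fit(x, times, events)
            return np.nan if fit.non_estimable else fit.p(other)
        from .survival import logrank_test

        _, p = logrank_test(times, events, df[other].to_numpy())
        return p
    ta, tb = types[a], types[b]
    if ta == "categorical" and tb == "categorical":
        table = pd.crosstab(df[a], df[b])
        if table.shape == (2, 2):
            return float(stats.fisher_exact(table.to_numpy())[1])
        return float(stats.chi2_contingency(table.to_numpy())[1])
    if ta == "continuous" and tb == "continuous":
        try:
            return spearman_corr(
                pd.to_numeric(df[a]).to_numpy(), pd.to_numeric(df[b]).to_numpy()
            )[1]
        except InvalidParameterError:
            return np.nan
    cat, cont = (a, b) if ta == "categorical" else (b, a)
    groups = [
        pd.to_numeric(sub[cont]).to_numpy()
        for _, sub in df.groupby(cat, observed=True)
    ]
    return float(stats.kruskal(*groups)[1])


def category_percentages(counts: Mapping[str, int]) -> dict[str, float]:
    """Percent of total per category, rounded to one decimal."""
    total = sum(counts.values())
    if total <= 0:
        raise InvalidParameterError("counts must sum to a positive total")
    return {k: round(100.0 * v / total, 1) for k, v in counts.items()}
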