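"""Survival analysis: KM curves, log-rank tests, Cox models and the
elastic-net-driven selection of prognostic population dynamics.

The selection cascade mirrors the emulated analysis: an elastic-net
penalized Cox model on the patients × populations matrix of presence
changes (FU − BL, encoded −1/0/+1) proposes candidate populations; a
univariate screen drops candidates whose fits are non-estimable or whose
Wald and log-rank verdicts disagree; the survivors enter one joint
multivariate Cox model, and populations with an independent association
(Wald p < 0.05) feed the combinatorial disappearance model.

Cox fits use the Efron tie approximation throughout (lifelines); the
elastic-net path is computed by scikit-survival's glmnet port, with λ
chosen by 10-fold cross-validated partial-likelihood deviance on the
training 80% and α chosen by concordance on the held-out 20%.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold, train_test_split
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

from .errors import InvalidParameterError, NonIdentifiableError
from .tmaes import DynamicsRecord

logger = logging.getLogger(__name__)

#: |beta| beyond which a coefficient is treated as diverging (monotone
#: likelihood / separation) rather than estimated.
SEPARATION_BOUND = 10.0


@dataclass
class SurvivalRecord:
    """Per-patient outcome: times in months from the first ICB dose."""

    patient_id: str
    os_time: float
    os_event: int
    pfs_time: float | None = None
    pfs_event: int | None = None
    covariates: dict = field(default_factory=dict)


def records_to_frame(records: Iterable[SurvivalRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "os_time": r.os_time,
            "os_event": r.os_event,
            "pfs_time": r.pfs_time,
            "pfs_event": r.pfs_event,
        }
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


@dataclass
class KMCurve:
    times: np.ndarray  # distinct observed times, ascending
    survival: np.ndarray  # S(t) just after each time
    at_risk: np.ndarray  # subjects at risk at each time
    median: float  # inf if S never crosses 0.5

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t."""
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


def km_fit(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Product-limit survival estimate (censored subjects at risk at their time)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise InvalidParameterError("km_fit needs at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    grid = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(grid).to_numpy()
    at_risk = table["at_risk"].to_numpy()
    keep = grid > 0
    median = float(kmf.median_survival_time_)
    return KMCurve(grid[keep], surv[keep], at_risk[keep], median)


def logrank_test(
    times: Sequence[float], events: Sequence[int], group_labels: Sequence
) -> tuple[float, float]:
    """k-group log-rank test; returns (chi-square, p) with k−1 df."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(group_labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise InvalidParameterError("log-rank needs >= 2 nonempty groups")
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxResult:
    """Per-covariate estimates plus model-level diagnostics.

    ``summary`` has one row per covariate with columns coef, hr,
    ci_lower, ci_upper, se, p.  ``non_estimable`` marks monotone
    likelihood / separation or convergence failure; in that case the
    numeric fields should not be interpreted.
    """

    summary: pd.DataFrame | None
    concordance: float | None = None
    model_p: float | None = None
    non_estimable: bool = False
    reason: str | None = None

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])

    def p(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "p"])


def cox_fit(
    X: pd.DataFrame,
    times: Sequence[float],
    events: Sequence[int],
    ties: str = "efron",
) -> CoxResult:
    """Cox proportional-hazards fit maximizing the Efron partial likelihood.

    Raises NonIdentifiableError for a covariate constant across subjects
    or if no events occurred; flags (rather than hides) monotone-
    likelihood divergence as ``non_estimable``.
    """
    X = pd.DataFrame(X).reset_index(drop=True)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 1:
        raise NonIdentifiableError("no events observed")
    for col in X.columns:
        if X[col].nunique() <= 1:
            raise NonIdentifiableError(f"covariate {col!r} is constant")
    df = X.copy()
    df["_time"] = times
    df["_event"] = events
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            cph.fit(
                df,
                duration_col="_time",
                event_col="_event",
                fit_options={"precision": 1e-9},
            )
        convergence_notes = [
            str(w.message) for w in caught if issubclass(w.category, ConvergenceWarning)
        ]
    except (ConvergenceError, np.linalg.LinAlgError) as exc:
        return CoxResult(
            summary=None, non_estimable=True, reason=f"convergence failure: {exc}"
        )
    sm = cph.summary
    out = pd.DataFrame(
        {
            "coef": sm["coef"],
            "hr": sm["exp(coef)"],
            "ci_lower": np.exp(sm["coef lower 95%"]),
            "ci_upper": np.exp(sm["coef upper 95%"]),
            "se": sm["se(coef)"],
            "p": sm["p"],
        }
    )
    out.index = list(X.columns)
    diverged = out["coef"].abs() > SEPARATION_BOUND
    if diverged.any():
        return CoxResult(
            summary=out,
            concordance=float(cph.concordance_index_),
            non_estimable=True,
            reason="monotone likelihood: |coef| > "
            f"{SEPARATION_BOUND} for {list(out.index[diverged])}",
        )
    if convergence_notes:
        return CoxResult(
            summary=out,
            concordance=float(cph.concordance_index_),
            non_estimable=True,
            reason="; ".join(convergence_notes),
        )
    lrt = cph.log_likelihood_ratio_test()
    return CoxResult(
        summary=out,
        concordance=float(cph.concordance_index_),
        model_p=float(lrt.p_value),
    )


# ---------------------------------------------------------------------------
# elastic-net Cox selection


@dataclass
class ElasticNetConfig:
    """Hyperparameters of the penalized-Cox selection step.

    The penalty is λ·[α‖β‖₁ + (1−α)‖β‖₂²/2]; α is scanned over
    ``alpha_grid`` and picked by concordance on a held-out split, λ by
    cross-validated partial-likelihood deviance on the training split
    (``cv_rule`` = "1se" keeps the most parsimonious λ within one
    standard error of the minimum; "min" takes the minimum itself).
    """

    alpha_grid: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 11))
    train_frac: float = 0.8
    cv_folds: int = 10
    cv_rule: str = "1se"
    n_lambdas: int = 30
    lambda_min_ratio: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 <= a <= 1 for a in self.alpha_grid):
            raise InvalidParameterError("alpha values must be in [0, 1]")
        if not 0 < self.train_frac < 1:
            raise InvalidParameterError("train_frac must be in (0, 1)")
        if self.cv_rule not in ("1se", "min"):
            raise InvalidParameterError("cv_rule must be '1se' or 'min'")


@dataclass
class SelectionResult:
    selected: list[str]
    alpha: float | None
    lam: float | None
    coefs: pd.Series | None
    test_concordance: float | None
    per_alpha: pd.DataFrame | None = None


def _breslow_loglik(eta: np.ndarray, times: np.ndarray, events: np.ndarray) -> np.ndarray:
    """Breslow log partial likelihood for each column of eta (n × L)."""
    eta = np.atleast_2d(eta.T).T  # ensure 2-D (n, L)
    order = np.argsort(-times, kind="stable")
    eta_o = eta[order]
    t_o = times[order]
    e_o = events[order]
    log_cum = np.logaddexp.accumulate(eta_o, axis=0)
    n = len(t_o)
    ll = np.zeros(eta.shape[1])
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t_o[j + 1] == t_o[i]:
            j += 1
        lse = log_cum[j]
        for k in range(i, j + 1):
            if e_o[k]:
                ll += eta_o[k] - lse
        i = j + 1
    return ll


def _cv_deviance(
    X: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    alpha: float,
    lambdas: np.ndarray,
    config: ElasticNetConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-validated partial-likelihood deviance per λ (mean, se over folds).

    Uses the difference between the full-training and leave-fold-out log
    partial likelihoods evaluated at the fold model's coefficients (the
    Verweij–Van Houwelingen scheme, as in cv.glmnet for Cox).
    """
    # folds cannot outnumber the smaller event stratum (small-cohort guard)
    class_min = int(np.bincount(events).min()) if len(np.unique(events)) > 1 else len(events)
    n_splits = max(2, min(config.cv_folds, class_min))
    if n_splits < config.cv_folds:
        logger.info("reducing CV folds from %d to %d", config.cv_folds, n_splits)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=config.seed)
    devs = []
    for keep_idx, _ in skf.split(X, events):
        model = CoxnetSurvivalAnalysis(l1_ratio=alpha, alphas=lambdas, tol=1e-6)
        y_sub = Surv.from_arrays(events[keep_idx].astype(bool), times[keep_idx])
        try:
            model.fit(X[keep_idx], y_sub)
        except (ArithmeticError, ValueError):  # pragma: no cover - degenerate fold
            continue
        coefs = _coefs_at(model, lambdas)  # (p, L)
        ll_full = _breslow_loglik(X @ coefs, times, events)
        ll_sub = _breslow_loglik(X[keep_idx] @ coefs, times[keep_idx], events[keep_idx])
        devs.append(-2.0 * (ll_full - ll_sub))
    devs = np.asarray(devs)
    if devs.size == 0:
        raise NonIdentifiableError("all cross-validation folds failed")
    return devs.mean(axis=0), devs.std(axis=0, ddof=1) / math.sqrt(devs.shape[0])


def _coefs_at(model: CoxnetSurvivalAnalysis, lambdas: np.ndarray) -> np.ndarray:
    """Coefficient matrix (p × L) aligned to the requested λ sequence."""
    fitted = np.asarray(model.alphas_)
    coefs = np.zeros((model.coef_.shape[0], len(lambdas)))
    for j, lam in enumerate(lambdas):
        k = int(np.argmin(np.abs(fitted - lam)))
        coefs[:, j] = model.coef_[:, k]
    return coefs


def elastic_net_select(
    delta: pd.DataFrame,
    survival: pd.DataFrame,
    config: ElasticNetConfig = ElasticNetConfig(),
) -> SelectionResult:
    """Select population-dynamics columns with nonzero penalized-Cox weight.

    ``delta`` is patients × populations (−1/0/+1 presence changes);
    ``survival`` must carry os_time/os_event indexed or keyed by the same
    patients.  Returns the selected populations with the winning (α, λ).
    An all-zero delta matrix yields an empty selection (logged), not an
    error.
    """
    surv = survival.set_index("patient_id") if "patient_id" in survival else survival
    surv = surv.loc[delta.index]
    times = surv["os_time"].to_numpy(dtype=float)
    events = surv["os_event"].to_numpy(dtype=int)

    keep_cols = [c for c in delta.columns if delta[c].nunique() > 1]
    if not keep_cols:
        logger.info("elastic_net_select: no varying columns; empty selection")
        return SelectionResult([], None, None, None, None)
    X = delta[keep_cols].to_numpy(dtype=float)

    idx = np.arange(len(delta))
    train, test = train_test_split(
        idx,
        test_size=1.0 - config.train_frac,
        stratify=events,
        random_state=config.seed,
    )
    rows = []
    best = None
    for alpha in config.alpha_grid:
        if alpha == 0:
            continue  # pure ridge has no sparse path; grid starts at 0.1
        path_model = CoxnetSurvivalAnalysis(
            l1_ratio=alpha,
            n_alphas=config.n_lambdas,
            alpha_min_ratio=config.lambda_min_ratio,
            tol=1e-6,
        )
        y_train = Surv.from_arrays(events[train].astype(bool), times[train])
        path_model.fit(X[train], y_train)
        lambdas = np.asarray(path_model.alphas_)
        mean_dev, se_dev = _cv_deviance(
            X[train], times[train], events[train], alpha, lambdas, config
        )
        j_min = int(np.argmin(mean_dev))
        if config.cv_rule == "1se":
            limit = mean_dev[j_min] + se_dev[j_min]
            eligible = np.nonzero(mean_dev <= limit)[0]
            # λ path is decreasing; the smallest index is the largest λ
            j_star = int(eligible.min())
        else:
            j_star = j_min
        lam = float(lambdas[j_star])
        beta = _coefs_at(path_model, np.array([lam]))[:, 0]
        risk_test = X[test] @ beta
        if np.ptp(risk_test) == 0:
            cindex = 0.5
        else:
            cindex = float(
                concordance_index_censored(
                    events[test].astype(bool), times[test], risk_test
                )[0]
            )
        n_selected = int(np.sum(beta != 0))
        rows.append(
            {
                "alpha": alpha,
                "lambda": lam,
                "test_concordance": cindex,
                "n_selected": n_selected,
            }
        )
        key = (cindex, -n_selected, alpha)
        if best is None or key > best[0]:
            best = (key, alpha, lam, beta, cindex)

    per_alpha = pd.DataFrame(rows)
    _, alpha_star, lam_star, beta_star, cindex_star = best
    coefs = pd.Series(beta_star, index=keep_cols)
    selected = [c for c in keep_cols if coefs[c] != 0]
    if not selected:
        logger.info("elastic_net_select: empty selection at alpha=%s", alpha_star)
    return SelectionResult(
        selected, alpha_star, lam_star, coefs, cindex_star, per_alpha
    )


def penalized_cox_coefs(
    X: pd.DataFrame,
    times: Sequence[float],
    events: Sequence[int],
    alpha: float,
    lam: float,
    tol: float = 1e-9,
) -> pd.Series:
    """Elastic-net Cox coefficients at a single fixed (α, λ)."""
    model = CoxnetSurvivalAnalysis(l1_ratio=alpha, alphas=[lam], tol=tol)
    y = Surv.from_arrays(
        np.asarray(events, dtype=int).astype(bool), np.asarray(times, dtype=float)
    )
    model.fit(np.asarray(X, dtype=float), y)
    return pd.Series(model.coef_[:, 0], index=list(X.columns))


# ---------------------------------------------------------------------------
# univariate screen and multivariate model


def univariate_screen(
    candidates: Sequence[str],
    delta: pd.DataFrame,
    survival: pd.DataFrame,
) -> tuple[list[str], dict[str, dict]]:
    """Drop candidates with unreliable univariate behaviour.

    A candidate is excluded iff (a) its univariate Cox fit is
    non-estimable (constant column, separation, monotone likelihood) or
    (b) its Wald and log-rank significance verdicts at 0.05 disagree.
    Returns (retained, per-candidate details).
    """
    surv = survival.set_index("patient_id") if "patient_id" in survival else survival
    surv = surv.loc[delta.index]
    times = surv["os_time"].to_numpy(dtype=float)
    events = surv["os_event"].to_numpy(dtype=int)
    retained: list[str] = []
    details: dict[str, dict] = {}
    for cand in candidates:
        x = delta[cand]
        info: dict = {"candidate": cand}
        if x.nunique() <= 1:
            info.update(excluded=True, reason="non-estimable: constant column")
            details[cand] = info
            continue
        try:
            fit = cox_fit(x.to_frame(), times, events)
        except NonIdentifiableError as exc:
            info.update(excluded=True, reason=f"non-estimable: {exc}")
            details[cand] = info
            continue
        if fit.non_estimable:
            info.update(excluded=True, reason=f"non-estimable: {fit.reason}")
            details[cand] = info
            continue
        wald_p = fit.p(cand)
        _, lr_p = logrank_test(times, events, x.to_numpy())
        agree = (wald_p < 0.05) == (lr_p < 0.05)
        info.update(
            excluded=not agree,
            reason=None if agree else "Wald/log-rank verdicts disagree",
            wald_p=wald_p,
            logrank_p=lr_p,
            hr=fit.hr(cand),
        )
        details[cand] = info
        if agree:
            retained.append(cand)
    return retained, details


def multivariate_cox(
    populations: Sequence[str], delta: pd.DataFrame, survival: pd.DataFrame
) -> CoxResult:
    """Joint Cox model of all retained populations (no stepwise selection)."""
    surv = survival.set_index("patient_id") if "patient_id" in survival else survival
    surv = surv.loc[delta.index]
    return cox_fit(
        delta[list(populations)],
        surv["os_time"].to_numpy(dtype=float),
        surv["os_event"].to_numpy(dtype=int),
    )


@dataclass
class CascadeResult:
    selection: SelectionResult
    retained: list[str]
    screen_details: dict[str, dict]
    multivariate: CoxResult | None
    independent: list[str]  # multivariate Wald p < 0.05


def select_populations_cascade(
    delta: pd.DataFrame,
    survival: pd.DataFrame,
    config: ElasticNetConfig = ElasticNetConfig(),
) -> CascadeResult:
    """Full elastic-net → univariate screen → multivariate Cox cascade."""
    selection = elastic_net_select(delta, survival, config)
    if not selection.selected:
        return CascadeResult(selection, [], {}, None, [])
    retained, details = univariate_screen(selection.selected, delta, survival)
    if not retained:
        return CascadeResult(selection, [], details, None, [])
    try:
        multi = multivariate_cox(retained, delta, survival)
    except NonIdentifiableError:
        return CascadeResult(selection, retained, details, None, [])
    if multi.non_estimable or multi.summary is None:
        return CascadeResult(selection, retained, details, multi, [])
    independent = [c for c in retained if multi.p(c) < 0.05]
    return CascadeResult(selection, retained, details, multi, independent)


# ---------------------------------------------------------------------------
# combinatorial disappearance model


@dataclass
class CombinatorialResult:
    flags: pd.Series  # 1 iff >=1 query population disappeared in the patient
    km_flagged: KMCurve | None
    km_unflagged: KMCurve | None
    logrank_p: float | None  # None if only one group present
    cox: CoxResult | None
    note: str | None = None


def combinatorial_model(
    dynamics: Iterable[DynamicsRecord],
    populations: set[str] | Sequence[str],
    survival: pd.DataFrame,
) -> CombinatorialResult:
    """Flag patients losing >= 1 of the given populations; model OS by flag."""
    populations = set(populations)
    if not populations:
        raise InvalidParameterError("populations must be nonempty")
    dyn = list(dynamics)
    flags = pd.Series(
        {r.patient_id: int(bool(r.disappearing & populations)) for r in dyn}
    )
    surv = survival.set_index("patient_id") if "patient_id" in survival else survival
    surv = surv.loc[flags.index]
    times = surv["os_time"].to_numpy(dtype=float)
    events = surv["os_event"].to_numpy(dtype=int)
    f = flags.to_numpy()

    km1 = km_fit(times[f == 1], events[f == 1]) if (f == 1).any() else None
    km0 = km_fit(times[f == 0], events[f == 0]) if (f == 0).any() else None
    if (f == 1).any() and (f == 0).any():
        _, lr_p = logrank_test(times, events, f)
        try:
            cox = cox_fit(pd.DataFrame({"disappearance": f}), times, events)
        except NonIdentifiableError as exc:
            cox = CoxResult(summary=None, non_estimable=True, reason=str(exc))
        note = None
    else:
        lr_p, cox = None, None
        note = "all patients share one flag; log-rank not applicable"
    return CombinatorialResult(flags, km1, km0, lr_p, cox, note)
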