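"""KM, log-rank, Cox, elastic-net selection, screen and combinatorial model."""

import numpy as np
import pandas as pd
import pytest

from dexdyn.errors import InvalidParameterError, NonIdentifiableError
from dexdyn.survival import (
    CascadeResult,
    ElasticNetConfig,
    combinatorial_model,
    cox_fit,
    elastic_net_select,
    km_fit,
    logrank_test,
    penalized_cox_coefs,
    select_populations_cascade,
    univariate_screen,
)
from dexdyn.synthlib import SimParams, simulate_informative_cohort
from dexdyn.tmaes import classify_dynamics


# ---------------------------------------------------------------------------
# Kaplan-Meier


class TestKM:
    def test_all_censored_survival_stays_one(self):
        km = km_fit([3, 5, 7], [0, 0, 0])
        assert np.allclose(km.survival, 1.0)
        assert km.median == np.inf

    def test_no_censoring_reduces_to_empirical_survival(self):
        km = km_fit([1, 2, 3, 4], [1, 1, 1, 1])
        assert np.allclose(km.survival, [0.75, 0.5, 0.25, 0.0])

    def test_hand_computed_product_limit_with_censoring(self):
        # deaths at 1,2,4,5; censored at 3:
        # S = 4/5, 4/5*3/4=3/5, (censor) 3/5, 3/5*1/2=3/10, 0
        km = km_fit([1, 2, 3, 4, 5], [1, 1, 0, 1, 1])
        assert km.survival_at(1) == pytest.approx(0.8)
        assert km.survival_at(2) == pytest.approx(0.6)
        assert km.survival_at(3) == pytest.approx(0.6)
        assert km.survival_at(4) == pytest.approx(0.3)
        assert km.survival_at(5) == pytest.approx(0.0)
        assert km.median == pytest.approx(4.0)

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidParameterError):
            km_fit([], [])


# ---------------------------------------------------------------------------
# log-rank


def _logrank_oracle(times, events, groups):
    """Direct O−E/V two-group log-rank computation."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n - d) * n1 * (n - n1) / (n**2 * (n - 1))
    chi2 = o_minus_e**2 / var
    from scipy.stats import chi2 as chi2_dist

    return chi2, chi2_dist.sf(chi2, 1)


class TestLogrank:
    def test_identical_groups_give_null_result(self):
        t = [1, 2, 3, 4] * 2
        e = [1, 1, 1, 1] * 2
        g = [0] * 4 + [1] * 4
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(10, size=30).round(1) + 0.1
        e = rng.integers(0, 2, size=30)
        e[:5] = 1  # ensure events
        g = rng.integers(0, 2, size=30)
        chi2, p = logrank_test(t, e, g)
        chi2_o, p_o = _logrank_oracle(t, e, g)
        assert chi2 == pytest.approx(chi2_o, abs=1e-10)
        assert p == pytest.approx(p_o, abs=1e-10)

    def test_invariant_to_group_relabeling(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(10, size=40)
        e = rng.integers(0, 2, size=40)
        e[0] = 1
        g = rng.integers(0, 2, size=40)
        assert logrank_test(t, e, g) == pytest.approx(logrank_test(t, e, 1 - g))

    def test_single_group_rejected(self):
        with pytest.raises(InvalidParameterError):
            logrank_test([1, 2], [1, 1], [0, 0])

    def test_permutation_calibration(self):
        """Under label permutation the p<0.05 rate sits near 5%."""
        rng = np.random.default_rng(17)
        n = 40
        t = rng.exponential(10, size=n)
        e = (rng.random(n) < 0.8).astype(int)
        g = np.array([0] * (n // 2) + [1] * (n // 2))
        hits = 0
        n_perm = 2000
        for _ in range(n_perm):
            rng.shuffle(g)
            _, p = logrank_test(t, e, g)
            hits += p < 0.05
        assert 0.03 <= hits / n_perm <= 0.07


# ---------------------------------------------------------------------------
# Cox


class TestCox:
    def test_constant_covariate_rejected(self):
        with pytest.raises(NonIdentifiableError):
            cox_fit(pd.DataFrame({"x": [1, 1, 1, 1]}), [1, 2, 3, 4], [1, 1, 0, 1])

    def test_no_events_rejected(self):
        with pytest.raises(NonIdentifiableError):
            cox_fit(pd.DataFrame({"x": [0, 1]}), [1, 2], [0, 0])

    def test_null_covariate_ci_coverage(self):
        """95% CI covers HR=1 in about 95% of null replicates."""
        rng = np.random.default_rng(0)
        covered = 0
        n_rep = 100
        for _ in range(n_rep):
            n = 80
            x = rng.integers(0, 2, size=n)
            t = rng.exponential(10, size=n)
            e = (rng.random(n) < 0.8).astype(int)
            fit = cox_fit(pd.DataFrame({"x": x}), t, e)
            if fit.non_estimable:
                continue
            covered += fit.summary.loc["x", "ci_lower"] <= 1 <= fit.summary.loc["x", "ci_upper"]
        assert covered >= 88

    def test_two_group_exponential_recovery(self):
        """True HR 0.25 at n=200: CI covers log(0.25) in >=90% of seeds."""
        hit = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x = rng.integers(0, 2, size=200)
            lam = np.where(x == 1, 0.25 * 0.05, 0.05)
            t = rng.exponential(1 / lam)
            c = rng.exponential(1 / 0.01, size=200)
            times = np.minimum(t, c)
            events = (t <= c).astype(int)
            fit = cox_fit(pd.DataFrame({"x": x}), times, events)
            lo = np.log(fit.summary.loc["x", "ci_lower"])
            hi = np.log(fit.summary.loc["x", "ci_upper"])
            hit += lo <= np.log(0.25) <= hi
        assert hit >= 0.9 * n_seeds

    def test_perfect_separation_flagged(self):
        times = [1, 2, 3, 4, 10, 11, 12, 13]
        events = [1, 1, 1, 1, 0, 0, 0, 0]
        x = [1, 1, 1, 1, 0, 0, 0, 0]
        fit = cox_fit(pd.DataFrame({"x": x}), times, events)
        assert fit.non_estimable
        assert fit.reason is not None


# ---------------------------------------------------------------------------
# elastic net


def _toy_cohort(seed=0, n=120):
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    x3 = rng.normal(size=n)
    lam = 0.05 * np.exp(0.8 * x1 - 0.5 * x2)
    t = rng.exponential(1 / lam)
    c = rng.exponential(1 / 0.01, size=n)
    X = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
    return X, np.minimum(t, c), (t <= c).astype(int)


class TestElasticNet:
    def test_full_shrinkage_selects_nothing(self):
        X, t, e = _toy_cohort()
        coefs = penalized_cox_coefs(X, t, e, alpha=1.0, lam=1e6)
        assert (coefs == 0).all()

    def test_near_zero_penalty_matches_unpenalized_fit(self):
        X, t, e = _toy_cohort()
        coefs = penalized_cox_coefs(X, t, e, alpha=0.5, lam=1e-9, tol=1e-12)
        fit = cox_fit(X, t, e)
        assert np.allclose(coefs, fit.summary["coef"], atol=1e-6)

    def test_lasso_vs_ridge_on_duplicated_column(self):
        """Lasso keeps one of an identical pair; near-ridge shares the weight."""
        rng = np.random.default_rng(4)
        n = 100
        z = rng.integers(0, 2, size=n).astype(float)
        noise = rng.normal(size=n)
        lam_h = 0.05 * np.exp(-1.5 * z)
        t = rng.exponential(1 / lam_h)
        X = pd.DataFrame({"a": z, "b": z.copy(), "c": noise})
        e = np.ones(n, dtype=int)
        lasso = penalized_cox_coefs(X, t, e, alpha=1.0, lam=0.05)
        assert (lasso[["a", "b"]] != 0).sum() <= 1
        ridge = penalized_cox_coefs(X, t, e, alpha=0.1, lam=0.05)
        assert ridge["a"] != 0 and ridge["b"] != 0
        assert ridge["a"] == pytest.approx(ridge["b"], rel=1e-3)

    def test_all_zero_delta_yields_empty_selection(self):
        delta = pd.DataFrame(
            0, index=[f"P{i}" for i in range(20)], columns=["p1", "p2"]
        )
        surv = pd.DataFrame(
            {
                "patient_id": delta.index,
                "os_time": np.arange(1, 21, dtype=float),
                "os_event": [1] * 20,
            }
        )
        res = elastic_net_select(delta, surv, ElasticNetConfig(cv_folds=3))
        assert res.selected == []

    def test_planted_populations_recovered(self):
        params = SimParams(n_patients=150, library_size=60, seed=8)
        co = simulate_informative_cohort(params, n_informative=3)
        res = elastic_net_select(
            co.delta, co.clinical, ElasticNetConfig(seed=8)
        )
        assert set(co.informative_ids) <= set(res.selected)


# ---------------------------------------------------------------------------
# univariate screen + cascade


class TestScreen:
    def _delta_and_surv(self, seed=12):
        params = SimParams(n_patients=120, library_size=40, seed=seed)
        co = simulate_informative_cohort(params, n_informative=2)
        return co

    def test_all_zero_column_excluded(self):
        co = self._delta_and_surv()
        delta = co.delta.copy()
        delta["dead_col"] = 0
        retained, details = univariate_screen(
            ["dead_col"], delta, co.clinical
        )
        assert retained == []
        assert "non-estimable" in details["dead_col"]["reason"]

    def test_planted_column_retained_with_protective_hr(self):
        co = self._delta_and_surv()
        target = co.informative_ids[0]
        retained, details = univariate_screen([target], co.delta, co.clinical)
        assert target in retained
        assert details[target]["hr"] < 1  # appearance is protective

    def test_monotone_likelihood_column_flagged(self):
        co = self._delta_and_surv()
        delta = co.delta.copy()
        clin = co.clinical.set_index("patient_id")
        clin = clin.copy()
        # single +1 in the patient with the longest, censored follow-up
        longest = clin["os_time"].idxmax()
        clin.loc[longest, "os_event"] = 0
        col = pd.Series(0, index=delta.index)
        col[longest] = 1
        delta["lonely"] = col
        retained, details = univariate_screen(
            ["lonely"], delta, clin.reset_index()
        )
        assert "lonely" not in retained
        assert "non-estimable" in details["lonely"]["reason"]

    def test_cascade_returns_consistent_sets(self):
        co = self._delta_and_surv(seed=15)
        res = select_populations_cascade(
            co.delta, co.clinical, ElasticNetConfig(seed=15)
        )
        assert isinstance(res, CascadeResult)
        assert set(res.retained) <= set(res.selection.selected)
        assert set(res.independent) <= set(res.retained)


# ---------------------------------------------------------------------------
# combinatorial disappearance model


def _flag_cohort(seed, n=150, hr=8.0):
    rng = np.random.default_rng(seed)
    flags = rng.random(n) < 0.4
    lam = 0.03 * np.where(flags, hr, 1.0)
    t = rng.exponential(1 / lam)
    c = rng.exponential(1 / 0.008, size=n)
    clin = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "os_time": np.minimum(t, c),
            "os_event": (t <= c).astype(int),
        }
    )
    dynamics = [
        classify_dynamics({"popX"} if f else set(), set(), f"P{i}")
        for i, f in enumerate(flags)
    ]
    return dynamics, clin, flags


class TestCombinatorial:
    def test_flag_logic(self):
        recs = [
            classify_dynamics(set(), set(), "P1"),  # nothing disappears
            classify_dynamics({"a", "q"}, {"a"}, "P2"),  # loses q
            classify_dynamics({"z"}, set(), "P3"),  # loses z (not queried)
        ]
        clin = pd.DataFrame(
            {
                "patient_id": ["P1", "P2", "P3"],
                "os_time": [5.0, 2.0, 7.0],
                "os_event": [1, 1, 1],
            }
        )
        res = combinatorial_model(recs, {"q", "r", "s"}, clin)
        assert res.flags.tolist() == [0, 1, 0]

    def test_empty_population_set_rejected(self):
        with pytest.raises(InvalidParameterError):
            combinatorial_model([], set(), pd.DataFrame())

    def test_single_flag_group_is_not_an_error(self):
        recs = [classify_dynamics(set(), set(), f"P{i}") for i in range(4)]
        clin = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(4)],
                "os_time": [1.0, 2.0, 3.0, 4.0],
                "os_event": [1, 1, 1, 0],
            }
        )
        res = combinatorial_model(recs, {"q"}, clin)
        assert res.logrank_p is None
        assert res.note is not None
        assert res.km_unflagged is not None

    def test_planted_deleterious_flag_recovered(self):
        """Planted HR >> 1 for the flagged group is recovered across seeds."""
        ok = 0
        for seed in range(10):
            dynamics, clin, _ = _flag_cohort(seed)
            res = combinatorial_model(dynamics, {"popX"}, clin)
            ok += (
                res.cox is not None
                and not res.cox.non_estimable
                and res.cox.hr("disappearance") > 1
                and res.logrank_p < 0.05
            )
        assert ok >= 9
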