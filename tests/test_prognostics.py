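"""Survival layer: Kaplan-Meier, log-rank (with a hand O/E/V oracle),
optimal cutoffs and their multiplicity inflation, Efron Cox fitting with
forward selection, Spearman correlations, and the 3-factor score."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nodalprog.config import ScoreConfig
from nodalprog.phantoms import CohortSpec, gen_cohort
from nodalprog.prognostics import (
    _efron_derivatives,
    cohort_scores,
    cox_fit,
    km_estimate,
    logrank_test,
    optimal_cutoff,
    prognostic_score,
    score_group_analysis,
    spearman_matrix,
    univariate_screen,
)


def logrank_oracle(times, events, groups):
    """Brute-force two-group log-rank: O/E/V tabulated at each event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups, int)
    o_minus_e, var = 0.0, 0.0
    for tj in np.unique(times[events == 1]):
        at_risk = times >= tj
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = ((times == tj) & (events == 1)).sum()
        d1 = ((times == tj) & (events == 1) & (groups == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def efron_loglik_oracle(beta, x, times, events):
    """Plain-loop Efron partial log-likelihood for a single covariate."""
    ll = 0.0
    w = np.exp(beta * x)
    for tj in np.unique(times[events == 1]):
        at_risk = times >= tj
        dead = (times == tj) & (events == 1)
        d = dead.sum()
        s_r, s_d = w[at_risk].sum(), w[dead].sum()
        ll += beta * x[dead].sum()
        for l in range(d):
            ll -= np.log(s_r - (l / d) * s_d)
    return ll


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survivor(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        km = km_estimate(times, np.ones(4, int))
        for t in [0.5, 1.0, 2.0, 3.5, 4.0]:
            assert km.rate_at(t) == pytest.approx((times > t).mean())

    def test_all_censored_stays_at_one(self):
        km = km_estimate([5.0, 10.0, 20.0], [0, 0, 0])
        assert km.rate_at(30.0) == 1.0

    def test_hand_product_limit_with_censoring(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        assert km.rate_at(2.5) == pytest.approx(2.0 / 3.0)
        assert km.rate_at(3.0) == pytest.approx(0.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_duplicated_groups_give_zero(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [1, 1, 0, 1, 1, 0]
        g = [0, 0, 0, 1, 1, 1]
        res = logrank_test(t, e, g)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)
        assert res["df"] == 1

    def test_matches_hand_oe_v_tabulation_on_separated_toy(self):
        t = np.array([1.0, 2.0, 3.0, 10.0, 10.0, 10.0])
        e = np.array([1, 1, 1, 0, 0, 0])
        g = np.array([1, 1, 1, 0, 0, 0])
        res = logrank_test(t, e, g)
        assert res["chi2"] == pytest.approx(logrank_oracle(t, e, g), rel=1e-10)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 40)
        e = rng.integers(0, 2, 40)
        t = np.maximum(t, 0.01)
        g = rng.integers(0, 2, 40)
        a = logrank_test(t, e, g)
        b = logrank_test(t, e, 1 - g)
        assert a["chi2"] == pytest.approx(b["chi2"])

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [1, 1], [0, 0])

    def test_type_one_error_within_band_on_null(self):
        """Empirical alpha of the 0.05-level test over 400 null cohorts."""
        rej = 0
        B = 400
        for b in range(B):
            spec = CohortSpec(n=69, covariates={"x": ("normal", 0, 1)},
                              beta={}, censor_window=(7.0, 49.0), seed=b)
            coh = gen_cohort(spec)
            g = (coh["x"] > coh["x"].median()).astype(int)
            rej += logrank_test(coh["time_months"], coh["event"], g)["p"] < 0.05
        assert 0.02 <= rej / B <= 0.08


class TestOptimalCutoff:
    def test_separable_cohort_puts_cutoff_in_gap(self):
        # higher covariate values fail early; clean gap between 5 and 9
        x = np.r_[np.full(15, 2.0) + np.arange(15) * 0.2,
                  np.full(15, 9.0) + np.arange(15) * 0.2]
        t = np.r_[np.full(15, 40.0), np.linspace(2, 12, 15)]
        e = np.r_[np.zeros(15, int), np.ones(15, int)]
        res = optimal_cutoff(x, t, e, variable="v")
        assert 4.8 < res.cutoff < 9.0
        assert res.orientation == "low"  # low values favorable

    def test_two_distinct_values_forced_midpoint(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        t = np.r_[np.full(10, 30.0), np.linspace(1, 10, 10)]
        e = np.r_[np.zeros(10, int), np.ones(10, int)]
        res = optimal_cutoff(x, t, e)
        assert res.cutoff == pytest.approx(0.5)
        assert res.n_low == res.n_high == 10

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            optimal_cutoff(np.ones(10), np.arange(1.0, 11.0), np.ones(10, int))

    def test_min_group_frac_respected(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        t = np.maximum(rng.exponential(20, 50), 0.1)
        e = rng.integers(0, 2, 50)
        res = optimal_cutoff(x, t, e, min_group_frac=0.2)
        assert min(res.n_low, res.n_high) >= 10

    def test_optimised_p_inflated_versus_prespecified_split(self):
        """On null data the searched cutoff yields anti-conservative
        p-values relative to a single median split (documented, not
        corrected)."""
        p_opt, p_med = [], []
        for b in range(40):
            spec = CohortSpec(n=40, covariates={"x": ("normal", 0, 1)},
                              beta={}, censor_window=(7.0, 49.0), seed=1000 + b)
            coh = gen_cohort(spec)
            x = coh["x"].to_numpy()
            t = coh["time_months"].to_numpy()
            e = coh["event"].to_numpy()
            p_opt.append(optimal_cutoff(x, t, e, min_group_frac=0.25).p)
            g = (x > np.median(x)).astype(int)
            p_med.append(logrank_test(t, e, g)["p"])
        assert np.mean(np.log(p_opt)) < np.mean(np.log(p_med))


class TestUnivariateScreen:
    def _cohort(self, n=80, seed=0, beta=None):
        spec = CohortSpec(
            n=n,
            covariates={"hb": ("normal", 14.0, 1.8), "x": ("normal", 0, 1)},
            beta=beta or {}, censor_window=(7.0, 49.0), seed=seed)
        return gen_cohort(spec)

    def test_supplied_cutoff_defines_arms_exactly(self):
        coh = self._cohort(seed=4)
        out = univariate_screen(coh, ["hb"], cutoffs={"hb": 14.3})
        row = out.iloc[0]
        assert row["cutoff"] == 14.3
        assert row["n_high"] == int((coh["hb"] > 14.3).sum())
        assert row["n_low"] == int((coh["hb"] <= 14.3).sum())

    def test_null_variable_p_uniform_over_replicates(self):
        ps = []
        for b in range(100):
            coh = self._cohort(n=60, seed=2000 + b)
            out = univariate_screen(coh, ["hb"], cutoffs={"hb": 14.0})
            ps.append(out.iloc[0]["p"])
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_horizon_beyond_followup_reads_km_plateau(self):
        coh = self._cohort(seed=5)
        out_36 = univariate_screen(coh, ["hb"], cutoffs={"hb": 14.0},
                                   horizon=500.0)
        t = coh["time_months"].to_numpy()
        e = coh["event"].to_numpy()
        hi = coh["hb"].to_numpy() > 14.0
        plateau = km_estimate(t[hi], e[hi]).rate_at(t.max())
        assert out_36.iloc[0]["rate_high_pct"] == pytest.approx(100 * plateau)

    def test_missing_variable_listed_not_fatal(self):
        coh = self._cohort()
        out = univariate_screen(coh, ["hb", "ghost"], cutoffs={"hb": 14.0})
        assert out.attrs["skipped"] == ["ghost"]
        assert list(out["variable"]) == ["hb"]


class TestCoxFit:
    def test_tied_pair_has_analytic_zero_optimum(self):
        df = pd.DataFrame({"time_months": [1.0, 1.0], "event": [1, 1],
                           "x": [1.0, 0.0]})
        fit = cox_fit(df, ["x"], selection=None)
        assert abs(fit.summary.loc["x", "coef"]) < 1e-4

    def test_two_subject_one_step_newton_closed_form(self):
        # first event (x=1): U(0) = 1 - 1/2, I(0) = 1/4 -> one step = 2
        x = np.array([[1.0], [0.0]])
        _, u, info = _efron_derivatives(
            np.zeros(1), x, np.array([1.0, 2.0]), np.array([1, 1]))
        assert (u / np.diag(info))[0] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_bruteforce_efron_grid_on_small_cohort(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        x = rng.integers(0, 2, n).astype(float)
        t = np.maximum(np.round(rng.exponential(12, n) * np.exp(-0.7 * x)), 1.0)
        e = rng.uniform(size=n) < 0.8
        df = pd.DataFrame({"time_months": t, "event": e.astype(int), "x": x})
        fit = cox_fit(df, ["x"], selection=None)
        grid = np.arange(-4.0, 4.0, 1e-3)
        lls = [efron_loglik_oracle(b, x, t, e.astype(int)) for b in grid]
        b0 = grid[int(np.argmax(lls))]
        fine = np.arange(b0 - 2e-3, b0 + 2e-3, 1e-5)
        lls = [efron_loglik_oracle(b, x, t, e.astype(int)) for b in fine]
        b_star = fine[int(np.argmax(lls))]
        assert abs(fit.summary.loc["x", "coef"] - b_star) < 1e-4

    def test_duplicated_covariate_never_enters(self):
        spec = CohortSpec(n=300, covariates={"a": ("normal", 0, 1)},
                          beta={"a": 0.8}, censor_window=(7.0, 49.0), seed=3)
        coh = gen_cohort(spec)
        coh["a_copy"] = coh["a"]
        fit = cox_fit(coh, ["a", "a_copy"], selection="forward")
        assert fit.selected == ["a"]

    def test_forward_selection_skips_noise(self):
        spec = CohortSpec(
            n=400,
            covariates={"signal": ("normal", 0, 1), "noise": ("normal", 0, 1)},
            beta={"signal": 0.9}, censor_window=(7.0, 49.0), seed=9)
        coh = gen_cohort(spec)
        fit = cox_fit(coh, ["noise", "signal"], selection="forward")
        assert fit.selected == ["signal"]
        assert fit.summary.loc["signal", "hr"] == pytest.approx(
            np.exp(fit.summary.loc["signal", "coef"]))
        lo, hi = fit.summary.loc["signal", ["ci_lower", "ci_upper"]]
        assert lo < fit.summary.loc["signal", "hr"] < hi

    def test_coefficient_bias_shrinks_with_n(self):
        biases = {}
        for n in (200, 2000):
            spec = CohortSpec(n=n, covariates={"x": ("normal", 0, 1)},
                              beta={"x": 0.7}, censor_window=(7.0, 49.0),
                              seed=21)
            fit = cox_fit(gen_cohort(spec), ["x"], selection=None)
            biases[n] = abs(fit.summary.loc["x", "coef"] - 0.7)
        assert biases[200] < 0.2
        assert biases[2000] < 0.06

    def test_empty_candidates_rejected(self):
        df = pd.DataFrame({"time_months": [1.0, 2.0], "event": [1, 1]})
        with pytest.raises(ValueError):
            cox_fit(df, [])


class TestSpearman:
    def test_self_and_negation(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=30)})
        df["neg"] = -df["x"]
        rho, _ = spearman_matrix(df, ["x", "neg"])
        assert rho.loc["x", "x"] == 1.0
        assert rho.loc["x", "neg"] == pytest.approx(-1.0)

    def test_constant_column_flagged_nan(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "c": [5.0] * 4})
        rho, p = spearman_matrix(df, ["x", "c"])
        assert np.isnan(rho.loc["x", "c"]) and np.isnan(p.loc["x", "c"])

    def test_multiplicative_construction_correlates(self):
        # TLG = mean SUV x MTV inherits strong rank correlation with both
        rng = np.random.default_rng(8)
        suv_mean = np.exp(rng.normal(2.0, 0.3, 100))
        mtv = np.exp(rng.normal(2.5, 1.0, 100))
        df = pd.DataFrame({"suv_mean": suv_mean, "mtv": mtv,
                           "tlg": suv_mean * mtv})
        rho, _ = spearman_matrix(df, ["suv_mean", "mtv", "tlg"])
        assert rho.loc["tlg", "mtv"] > 0.9


class TestPrognosticScore:
    def test_favorable_worked_example_scores_zero(self):
        res = prognostic_score(hb=15.9, ve=0.34, adc=0.78)
        assert res == {"score": 0, "group": "low"}

    def test_adverse_worked_example_scores_three(self):
        res = prognostic_score(hb=12.7, ve=0.07, adc=1.24)
        assert res == {"score": 3, "group": "high"}

    def test_boundary_values_count_as_risk(self):
        res = prognostic_score(hb=14.3, ve=0.23, adc=1.14)
        assert res["score"] == 3

    def test_missing_component_rejected(self):
        with pytest.raises(ValueError):
            prognostic_score(hb=14.0, ve=np.nan, adc=1.0)


class TestScoreGroupAnalysis:
    def _scored_cohort(self, n=200, seed=0, group_beta=1.2):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "hb": rng.normal(14.0, 1.8, n),
            "ve": np.exp(rng.normal(np.log(0.18), 0.7, n)),
            "adc": rng.normal(0.95, 0.18, n),
        })
        sc = cohort_scores(df)
        high = (sc["group"] == "high").to_numpy().astype(float)
        u = rng.uniform(size=n)
        t = 60.0 * (-np.log(u)) ** (1 / 1.2) * np.exp(-group_beta * high / 1.2)
        c = rng.uniform(7, 49, n)
        df["time_months"] = np.maximum(np.minimum(t, c), 1e-3)
        df["event"] = (t <= c).astype(int)
        df["zeros"] = 0
        return df

    def test_group_effect_recovered(self):
        df = self._scored_cohort(n=600, seed=2)
        rep = score_group_analysis(df)
        assert rep["valid"]
        assert rep["cox"]["hr"] > 1.5
        assert rep["logrank"]["p"] < 0.01
        assert rep["rate_high_pct"] < rep["rate_low_pct"]

    def test_zero_extra_factor_reduces_to_three_factor_analysis(self):
        df = self._scored_cohort(seed=3)
        a = score_group_analysis(df)
        b = score_group_analysis(df, extra_factor="zeros")
        assert a["cox"]["hr"] == pytest.approx(b["cox"]["hr"])
        assert a["score_counts"] == b["score_counts"]

    def test_constant_score_degenerates_with_flags(self):
        df = self._scored_cohort(seed=4)
        df["hb"] = 10.0
        df["ve"] = 0.05
        df["adc"] = 1.3  # everyone scores 3 -> one group
        rep = score_group_analysis(df)
        assert not rep["valid"]
        assert "logrank_error" in rep
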