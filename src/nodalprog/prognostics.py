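"""Survival statistics for pretreatment prognostic modelling.

Kaplan-Meier estimation, log-rank testing, log-rank-optimal cutoff
dichotomisation, a Table-shaped univariate screen of 3-year control
rates, forward-selection Cox proportional-hazards modelling (Efron tie
handling, score-test entry), Spearman correlations, and the additive
3-factor prognostic score (hemoglobin / ve / ADC) with group-level
analysis.

The optimal-cutoff search maximizes the log-rank statistic over
candidate splits and applies no multiplicity correction; the resulting
p-values are anti-conservative by construction (demonstrated in the test
suite, documented, deliberately not corrected).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .config import ScoreConfig

DEFAULT_HORIZON = 36.0  # months (3-year outcome)


def _validate_surv(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.shape != e.shape:
        raise ValueError("times and events must align")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    if not np.all(np.isin(e, [0, 1])):
        raise ValueError("events must be 0/1")
    return t, e.astype(int)


class KMEstimate:
    """Product-limit survival estimate with right censoring."""

    def __init__(self, times, events):
        t, e = _validate_surv(times, events)
        self._kmf = KaplanMeierFitter()
        self._kmf.fit(t, event_observed=e)
        self.n = t.size

    @property
    def survival(self) -> pd.DataFrame:
        """Step function as a DataFrame indexed by time."""
        return self._kmf.survival_function_

    def rate_at(self, t: float) -> float:
        """Survival probability at time t (includes events occurring at t)."""
        return float(self._kmf.predict(t))


def km_estimate(times, events) -> KMEstimate:
    """Kaplan-Meier estimator; ``rate_at(t)`` reads the step function."""
    return KMEstimate(times, events)


def logrank_test(times, events, groups) -> dict:
    """Log-rank chi-square test across >= 2 non-empty groups.

    Returns {chi2, p, df} with df = n_groups - 1.
    """
    t, e = _validate_surv(times, events)
    g = np.asarray(groups)
    if g.shape != t.shape:
        raise ValueError("groups must align with times")
    labels, counts = np.unique(g, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least 2 non-empty groups")
    res = multivariate_logrank_test(t, g, e)
    return {"chi2": float(res.test_statistic), "p": float(res.p_value),
            "df": int(labels.size - 1)}


@dataclass
class CutoffResult:
    """Log-rank-optimal dichotomisation of one covariate."""

    variable: str
    cutoff: float
    orientation: str  # which side is favorable: "high" or "low"
    chi2: float
    p: float
    n_low: int
    n_high: int


def optimal_cutoff(
    values, times, events,
    min_group_frac: float = 0.10,
    variable: str = "x",
    horizon: float = DEFAULT_HORIZON,
) -> CutoffResult:
    """Cutoff maximizing the log-rank statistic over candidate splits.

    Candidates are midpoints between sorted distinct observed values,
    restricted so each arm holds at least ``min_group_frac`` of the
    cohort; ties in chi-square break toward the more balanced split.
    """
    t, e = _validate_surv(times, events)
    x = np.asarray(values, dtype=float)
    if x.shape != t.shape:
        raise ValueError("values must align with times")
    distinct = np.unique(x)
    if distinct.size < 2:
        raise ValueError("covariate is constant")
    n = x.size
    min_n = max(1, int(np.ceil(min_group_frac * n)))
    candidates = 0.5 * (distinct[:-1] + distinct[1:])

    best = None
    for c in candidates:
        hi = x > c
        n_hi = int(hi.sum())
        n_lo = n - n_hi
        if n_hi < min_n or n_lo < min_n:
            continue
        res = logrank_test(t, e, hi.astype(int))
        balance = abs(n_hi - n_lo)
        key = (-res["chi2"], balance)
        if best is None or key < best[0]:
            best = (key, c, res, n_lo, n_hi)
    if best is None:
        raise ValueError("no candidate split satisfies the group-size constraint")
    _, cutoff, res, n_lo, n_hi = best
    hi = x > cutoff
    rate_hi = km_estimate(t[hi], e[hi]).rate_at(horizon)
    rate_lo = km_estimate(t[~hi], e[~hi]).rate_at(horizon)
    orientation = "high" if rate_hi >= rate_lo else "low"
    return CutoffResult(
        variable=variable, cutoff=float(cutoff), orientation=orientation,
        chi2=res["chi2"], p=res["p"], n_low=n_lo, n_high=n_hi,
    )


def univariate_screen(
    cohort: pd.DataFrame,
    variables: list[str],
    horizon: float = DEFAULT_HORIZON,
    cutoffs: dict | None = None,
    min_group_frac: float = 0.10,
) -> pd.DataFrame:
    """Dichotomised univariate screen of control rates at ``horizon``.

    Each variable is split at its supplied cutoff (if any) or at the
    log-rank-optimal cutoff, then Kaplan-Meier rates at the horizon and
    the log-rank p are reported per arm, mirroring a univariate-analysis
    table.  Missing variables are skipped and listed in the attribute
    ``skipped`` of the returned frame.
    """
    cutoffs = cutoffs or {}
    t, e = _validate_surv(cohort["time_months"], cohort["event"])
    rows = []
    skipped = []
    for var in variables:
        if var not in cohort.columns:
            skipped.append(var)
            continue
        x = np.asarray(cohort[var], dtype=float)
        if var in cutoffs:
            c = float(cutoffs[var])
            hi = x > c
            if hi.all() or (~hi).all():
                skipped.append(var)
                continue
            res = logrank_test(t, e, hi.astype(int))
            chi2, p = res["chi2"], res["p"]
        else:
            try:
                cr = optimal_cutoff(x, t, e, min_group_frac, variable=var,
                                    horizon=horizon)
            except ValueError:  # constant covariate or no admissible split
                skipped.append(var)
                continue
            c = cr.cutoff
            hi = x > c
            chi2, p = cr.chi2, cr.p
        rate_hi = km_estimate(t[hi], e[hi]).rate_at(horizon)
        rate_lo = km_estimate(t[~hi], e[~hi]).rate_at(horizon)
        rows.append({
            "variable": var,
            "cutoff": c,
            "n_high": int(hi.sum()),
            "n_low": int((~hi).sum()),
            "rate_high_pct": 100.0 * rate_hi,
            "rate_low_pct": 100.0 * rate_lo,
            "events_high": int(e[hi].sum()),
            "events_low": int(e[~hi].sum()),
            "chi2": chi2,
            "p": p,
        })
    out = pd.DataFrame(rows)
    out.attrs["skipped"] = skipped
    return out


# --- Cox proportional hazards with forward selection -----------------------


def _efron_derivatives(beta, x, time, event):
    """Efron partial log-likelihood, gradient and observed information.

    Handles tied event times with the Efron correction.  ``x`` is
    (n, p); returns (loglik, grad (p,), info (p, p)).
    """
    beta = np.asarray(beta, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    eta = x @ beta
    w = np.exp(eta)
    p = x.shape[1]
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for tj in np.unique(time[event == 1]):
        at_risk = time >= tj
        dead = (time == tj) & (event == 1)
        d = int(dead.sum())
        s_r = w[at_risk].sum()
        z_r = x[at_risk].T @ w[at_risk]
        q_r = (x[at_risk].T * w[at_risk]) @ x[at_risk]
        s_d = w[dead].sum()
        z_d = x[dead].T @ w[dead]
        q_d = (x[dead].T * w[dead]) @ x[dead]
        ll += eta[dead].sum()
        grad += x[dead].sum(axis=0)
        for l in range(d):
            f = l / d
            phi = s_r - f * s_d
            z = z_r - f * z_d
            q = q_r - f * q_d
            ll -= np.log(phi)
            grad -= z / phi
            info += q / phi - np.outer(z, z) / phi**2
    return ll, grad, info


def _score_test(x_sel, beta_sel, x_new, time, event):
    """Score test for adding one covariate at coefficient 0.

    Nuisance coefficients sit at their MLE, so the score vector is zero
    except for the new component; the statistic is U' I^{-1} U ~ chi2(1).
    """
    if x_sel is None or x_sel.shape[1] == 0:
        x_aug = x_new[:, None]
        beta_aug = np.zeros(1)
    else:
        x_aug = np.column_stack([x_sel, x_new])
        beta_aug = np.append(beta_sel, 0.0)
    _, u, info = _efron_derivatives(beta_aug, x_aug, time, event)
    try:
        stat = float(u @ np.linalg.solve(info, u))
    except np.linalg.LinAlgError:
        return np.nan, np.nan
    if stat < 0:
        stat = 0.0
    return stat, float(stats.chi2.sf(stat, df=1))


@dataclass
class CoxFit:
    """Forward-selection Cox model result."""

    selected: list[str]
    summary: pd.DataFrame          # coef, hr, ci_lower, ci_upper, p per selected var
    path: list[dict] = field(default_factory=list)
    excluded: dict = field(default_factory=dict)
    model: CoxPHFitter | None = None

    @property
    def hazard_ratios(self) -> pd.Series:
        return self.summary["hr"]


def _fit_cph(cohort, variables):
    cph = CoxPHFitter()
    df = cohort[["time_months", "event", *variables]].astype(float)
    cph.fit(df, duration_col="time_months", event_col="event",
            fit_options={"precision": 1e-9})
    return cph


def _summarize(cph: CoxPHFitter) -> pd.DataFrame:
    s = cph.summary
    return pd.DataFrame({
        "coef": s["coef"],
        "hr": s["exp(coef)"],
        "ci_lower": s["exp(coef) lower 95%"],
        "ci_upper": s["exp(coef) upper 95%"],
        "p": s["p"],
    })


def cox_fit(
    cohort: pd.DataFrame,
    candidates: list[str],
    selection: str | None = "forward",
    alpha_enter: float = 0.05,
) -> CoxFit:
    """Cox proportional-hazards fit with optional forward selection.

    Forward selection repeatedly adds the candidate with the smallest
    Efron score-test p-value while p < ``alpha_enter``; Wald hazard
    ratios with 95% CIs are reported for the selected model.  With
    ``selection=None`` all candidates enter directly.  Candidates whose
    information matrix is singular (collinear or constant) never enter.
    """
    if not candidates:
        raise ValueError("no candidate variables")
    t, e = _validate_surv(cohort["time_months"], cohort["event"])
    if e.sum() < 1:
        raise ValueError("no events in cohort")
    missing = [v for v in candidates if v not in cohort.columns]
    if missing:
        raise ValueError(f"missing candidate columns: {missing}")

    if selection is None:
        cph = _fit_cph(cohort, candidates)
        return CoxFit(selected=list(candidates), summary=_summarize(cph), model=cph)
    if selection != "forward":
        raise ValueError("selection must be 'forward' or None")

    selected: list[str] = []
    path: list[dict] = []
    excluded: dict = {}
    cph = None
    while True:
        remaining = [v for v in candidates if v not in selected and v not in excluded]
        if not remaining:
            break
        x_sel = (cohort[selected].to_numpy(dtype=float) if selected else None)
        beta_sel = cph.params_.to_numpy() if cph is not None else np.zeros(0)
        scores = []
        for v in remaining:
            x_new = cohort[v].to_numpy(dtype=float)
            if np.unique(x_new).size < 2:
                excluded[v] = "constant"
                continue
            stat, p = _score_test(x_sel, beta_sel, x_new, t, e)
            if not np.isfinite(stat):
                excluded[v] = "singular information (collinear)"
                continue
            scores.append((p, stat, v))
        if not scores:
            break
        scores.sort()
        p_best, stat_best, v_best = scores[0]
        if p_best >= alpha_enter:
            break
        try:
            cph = _fit_cph(cohort, selected + [v_best])
        except Exception as exc:  # monotone likelihood / separation
            excluded[v_best] = f"non-convergence: {exc}"
            cph = _fit_cph(cohort, selected) if selected else None
            continue
        selected.append(v_best)
        path.append({"variable": v_best, "score_chi2": stat_best, "p": p_best})

    if not selected:
        return CoxFit(selected=[], summary=pd.DataFrame(
            columns=["coef", "hr", "ci_lower", "ci_upper", "p"]),
            path=path, excluded=excluded)
    return CoxFit(selected=selected, summary=_summarize(cph), path=path,
                  excluded=excluded, model=cph)


def spearman_matrix(cohort: pd.DataFrame, variables: list[str]):
    """Pairwise Spearman rank correlations (mid-rank ties, two-sided p).

    Returns (rho, p) DataFrames; cells for constant columns are NaN.
    """
    k = len(variables)
    rho = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    pmat = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    for i, a in enumerate(variables):
        for j, b in enumerate(variables):
            if j <= i:
                continue
            xa = np.asarray(cohort[a], dtype=float)
            xb = np.asarray(cohort[b], dtype=float)
            ok = np.isfinite(xa) & np.isfinite(xb)
            if ok.sum() < 3 or np.unique(xa[ok]).size < 2 or np.unique(xb[ok]).size < 2:
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(xa[ok], xb[ok])
            rho.iloc[i, j] = rho.iloc[j, i] = r
            pmat.iloc[i, j] = pmat.iloc[j, i] = p
    return rho, pmat


def prognostic_score(hb, ve, adc, config: ScoreConfig | None = None) -> dict:
    """3-factor additive risk score and risk group.

    One point each for hb <= 14.3 g/dL, ve <= 0.23 and
    adc >= 1.14 (in 1e-3 mm^2/s units); the risk side of each cutoff is
    closed.  Group is "high" iff score >= 2.
    """
    config = config or ScoreConfig()
    vals = {"hb": hb, "ve": ve, "adc": adc}
    for k, v in vals.items():
        if v is None or not np.isfinite(v):
            raise ValueError(f"missing score component {k!r} (no partial scores)")
    score = int(hb <= config.hb_cutoff) + int(ve <= config.ve_cutoff) \
        + int(adc >= config.adc_cutoff)
    group = "high" if score >= config.high_risk_min_score else "low"
    return {"score": score, "group": group}


def cohort_scores(cohort: pd.DataFrame, config: ScoreConfig | None = None,
                  extra_factor: str | None = None) -> pd.DataFrame:
    """Per-patient score/group; with ``extra_factor`` the 0/1 column is
    added as a fourth point (score range 0-4, same high-risk threshold)."""
    config = config or ScoreConfig()
    rows = [prognostic_score(r.hb, r.ve, r.adc, config)["score"]
            for r in cohort.itertuples()]
    score = np.asarray(rows, dtype=int)
    if extra_factor is not None:
        extra = np.asarray(cohort[extra_factor], dtype=int)
        if not np.all(np.isin(extra, [0, 1])):
            raise ValueError("extra_factor must be 0/1")
        score = score + extra
    group = np.where(score >= config.high_risk_min_score, "high", "low")
    return pd.DataFrame({"score": score, "group": group}, index=cohort.index)


def score_group_analysis(
    cohort: pd.DataFrame,
    config: ScoreConfig | None = None,
    extra_factor: str | None = None,
    horizon: float = DEFAULT_HORIZON,
) -> dict:
    """Group-level outcome analysis of the prognostic score.

    Computes per-group Kaplan-Meier control rates at ``horizon``, the
    log-rank test and the Cox hazard ratio of high- vs low-score
    patients.  Degenerate groupings (all patients on one side) are
    reported with flags rather than raised.
    """
    config = config or ScoreConfig()
    t, e = _validate_surv(cohort["time_months"], cohort["event"])
    sc = cohort_scores(cohort, config, extra_factor)
    high = (sc["group"] == "high").to_numpy()
    report: dict = {
        "horizon_months": horizon,
        "n_low": int((~high).sum()),
        "n_high": int(high.sum()),
        "score_counts": sc["score"].value_counts().sort_index().to_dict(),
        "valid": True,
        "flags": [],
    }
    if report["n_low"] < 2 or report["n_high"] < 2:
        report["valid"] = False
        report["flags"].append("degenerate grouping: fewer than 2 patients in a group")
        report["logrank_error"] = "need at least 2 non-empty groups"
        return report
    report["rate_low_pct"] = 100.0 * km_estimate(t[~high], e[~high]).rate_at(horizon)
    report["rate_high_pct"] = 100.0 * km_estimate(t[high], e[high]).rate_at(horizon)
    report["logrank"] = logrank_test(t, e, high.astype(int))
    df = pd.DataFrame({"time_months": t, "event": e,
                       "high_score": high.astype(float)})
    fit = cox_fit(df, ["high_score"], selection=None)
    row = fit.summary.loc["high_score"]
    report["cox"] = {"hr": float(row["hr"]), "ci_lower": float(row["ci_lower"]),
                     "ci_upper": float(row["ci_upper"]), "p": float(row["p"])}
    return report
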