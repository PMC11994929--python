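"""Subtype-stratified treatment-effect statistics for a two-arm trial.

Response endpoints: ORR = (CR+PR)/n, DCR = (CR+PR+SD)/n, with not-evaluable
patients kept in the denominator; arm contrasts by Pearson chi-square or a
stratification-adjusted logistic likelihood-ratio test.  Time-to-event
endpoints: Kaplan-Meier curves with Brookmeyer-Crowley median confidence
intervals, log-rank tests, and (stratified / multivariable) Cox proportional
hazards models with Efron tie handling.  Rank-sum comparisons cover the
cell-line sensitivity contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

RESPONDER_BOR = {"CR", "PR"}
CONTROLLED_BOR = {"CR", "PR", "SD"}
BOR_CATEGORIES = ("CR", "PR", "SD", "PD", "NE")

_CHI2_95_DF1 = float(stats.chi2.ppf(0.95, 1))


@dataclass
class RateResult:
    n: int
    responders: int
    rate_percent: float
    test: str | None = None
    p_value: float | None = None


@dataclass
class ResponseRates:
    """ORR and DCR for one patient group."""

    orr: RateResult
    dcr: RateResult


@dataclass
class SurvivalFit:
    """Kaplan-Meier fit with Brookmeyer-Crowley median CI."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int
    n_events: int
    median: float | None
    median_ci: tuple[float | None, float | None]

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


@dataclass
class CoxResult:
    hr: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n: int
    n_events: int
    model: dict = field(default_factory=dict)


def compute_response_rates(bor: Sequence[str]) -> ResponseRates:
    """ORR and DCR (percent, one-decimal reporting) from best-overall-response
    categories; the denominator is the whole group including NE."""
    bor = list(bor)
    n = len(bor)
    if n == 0:
        raise ValueError("empty group")
    unknown = sorted(set(bor) - set(BOR_CATEGORIES))
    if unknown:
        raise ValueError(f"unknown BOR categories: {unknown}")
    n_orr = sum(b in RESPONDER_BOR for b in bor)
    n_dcr = sum(b in CONTROLLED_BOR for b in bor)
    return ResponseRates(
        orr=RateResult(n, n_orr, 100.0 * n_orr / n),
        dcr=RateResult(n, n_dcr, 100.0 * n_dcr / n),
    )


def chi_square_2x2(table: np.ndarray | Sequence[Sequence[int]]) -> tuple[float, float]:
    """Pearson chi-square without continuity correction on a 2×2 table."""
    table = np.asarray(table)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a non-negative 2×2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a table margin is zero")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def stratified_logistic_lrt(
    records: pd.DataFrame,
    outcome: str = "dcr",
    strata: Sequence[str] = (),
    treatment_col: str = "arm",
    treated_label: str = "abemaciclib",
) -> tuple[float, float]:
    """Likelihood-ratio test of the treatment term in a logistic model with
    stratification factors entered as adjustment covariates.

    Returns (two-sided p from the chi2(1) LRT, treatment odds ratio).
    """
    import statsmodels.api as sm

    if outcome not in ("orr", "dcr"):
        raise ValueError("outcome must be 'orr' or 'dcr'")
    good = RESPONDER_BOR if outcome == "orr" else CONTROLLED_BOR
    y = records["bor"].isin(good).astype(float)
    if y.nunique() < 2:
        raise ValueError(f"{outcome} outcome is constant; LRT undefined")
    arms = records[treatment_col]
    if arms.nunique() < 2:
        raise ValueError("both treatment arms must be present")
    treat = (arms == treated_label).astype(float)
    X_reduced = pd.DataFrame({"const": np.ones(len(records), float)}, index=records.index)
    if strata:
        dummies = pd.get_dummies(
            records[list(strata)].astype(str), drop_first=True, dtype=float
        )
        X_reduced = pd.concat([X_reduced, dummies], axis=1)
    X_full = pd.concat([X_reduced, treat.rename("treatment")], axis=1)
    try:
        fit_full = sm.Logit(y, X_full).fit(disp=0, maxiter=200)
        fit_reduced = sm.Logit(y, X_reduced).fit(disp=0, maxiter=200)
    except Exception as err:  # separation / non-convergence
        raise ValueError(f"logistic fit failed (possible separation): {err}") from err
    if not (fit_full.mle_retvals["converged"] and fit_reduced.mle_retvals["converged"]):
        raise ValueError("logistic fit did not converge (possible separation)")
    lrt = 2.0 * (fit_full.llf - fit_reduced.llf)
    p = float(stats.chi2.sf(max(lrt, 0.0), 1))
    odds_ratio = float(np.exp(fit_full.params["treatment"]))
    return p, odds_ratio


def _km_event_table(times: np.ndarray, events: np.ndarray):
    """Distinct event times with at-risk and event counts (vectorized)."""
    sorted_times = np.sort(times)
    uniq, d = np.unique(times[events == 1], return_counts=True)
    at_risk = len(times) - np.searchsorted(sorted_times, uniq, side="left")
    return uniq, at_risk, d


def km_fit(
    times: Sequence[float],
    events: Sequence[int],
    alpha: float = 0.05,
    transform: str = "loglog",
) -> SurvivalFit:
    """Kaplan-Meier product-limit fit with a Brookmeyer-Crowley median CI.

    The median is the smallest time with S(t) <= 0.5 (None when never
    reached).  Its CI inverts the test of S(t) = 0.5 over the observed event
    times: times where the squared standardized distance between the
    (transformed) survival estimate and 0.5 stays below the chi2(1) cutoff
    form the interval.  Greenwood's formula supplies the variance; the
    default transform is log(-log S).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("negative survival times")
    uniq, at_risk, d = _km_event_table(times, events)
    if uniq.size == 0:
        return SurvivalFit(
            times=np.array([]), survival=np.array([]), at_risk=np.array([]),
            n=len(times), n_events=0, median=None, median_ci=(None, None),
        )
    S = np.cumprod(1.0 - d / at_risk)
    greenwood = np.cumsum(d / (at_risk * (at_risk - d).clip(min=1e-300)))

    below = np.flatnonzero(S <= 0.5)
    median = float(uniq[below[0]]) if below.size else None

    cutoff = float(stats.chi2.ppf(1 - alpha, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        if transform == "loglog":
            ok = (S > 0) & (S < 1)
            stat = np.full_like(S, np.inf)
            psi = np.log(-np.log(S[ok]))
            var_psi = greenwood[ok] / (np.log(S[ok]) ** 2)
            target = np.log(-np.log(0.5))
            stat[ok] = np.where(var_psi > 0, (psi - target) ** 2 / var_psi, np.inf)
        elif transform == "identity":
            var_S = S**2 * greenwood
            stat = np.where(var_S > 0, (S - 0.5) ** 2 / var_S, np.inf)
        else:
            raise ValueError(f"unknown transform {transform!r}")
    inside = np.flatnonzero(stat <= cutoff)
    if inside.size == 0:
        ci: tuple[float | None, float | None] = (None, None)
    else:
        lo = float(uniq[inside[0]])
        # upper limit open ("not reached") when the last event time still
        # fails to reject, i.e. the data never pin the median from above
        hi = float(uniq[inside[-1]]) if inside[-1] < len(uniq) - 1 else None
        ci = (lo, hi)
    return SurvivalFit(
        times=uniq,
        survival=S,
        at_risk=at_risk,
        n=len(times),
        n_events=int(events.sum()),
        median=median,
        median_ci=ci,
    )


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> tuple[float, float]:
    """Unweighted log-rank chi2(1) statistic and two-sided p."""
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    events_a, events_b = np.asarray(events_a, int), np.asarray(events_b, int)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if events_a.sum() + events_b.sum() == 0:
        raise ValueError("log-rank undefined with zero events")
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def _encode_covariates(records: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Numeric covariates pass through; categoricals are dummy-encoded
    (first level dropped)."""
    parts = []
    for col in covariates:
        s = records[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float))
        else:
            parts.append(pd.get_dummies(s.astype(str), prefix=col, drop_first=True, dtype=float))
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=records.index)


def cox_fit(
    records: pd.DataFrame,
    duration_col: str,
    event_col: str,
    treatment_col: str,
    treated_label: str | None = None,
    strata: Sequence[str] = (),
    covariates: Sequence[str] = (),
    interactions: Sequence[tuple[str, str]] = (),
    ties: str = "efron",
) -> CoxResult:
    """Cox proportional-hazards fit reporting the treatment hazard ratio.

    ``strata`` columns get stratum-specific baseline hazards; ``covariates``
    enter as regression terms (categoricals dummy-encoded); ``interactions``
    are products of already-encoded numeric columns.  Ties are handled by
    Efron's method by default (Breslow available for cross-checking).
    """
    if records[event_col].sum() == 0:
        raise ValueError("Cox model undefined with zero events")
    treat = records[treatment_col]
    if treated_label is not None:
        treat = (treat == treated_label).astype(float)
    elif not pd.api.types.is_numeric_dtype(treat):
        raise ValueError("non-numeric treatment column requires treated_label")
    design = pd.DataFrame(
        {
            duration_col: records[duration_col].astype(float),
            event_col: records[event_col].astype(int),
            "treatment": treat.astype(float),
        },
        index=records.index,
    )
    if covariates:
        enc = _encode_covariates(records, covariates)
        design = pd.concat([design, enc], axis=1)
    for a, b in interactions:
        if a not in design.columns or b not in design.columns:
            raise ValueError(f"interaction terms {a}×{b} must name design columns")
        design[f"{a}:{b}"] = design[a] * design[b]
    strata_cols = list(strata)
    if ties == "efron":
        fit_frame = design.copy()
        if strata_cols:
            fit_frame[strata_cols] = records[strata_cols].astype(str)
        cph = CoxPHFitter()
        try:
            cph.fit(
                fit_frame,
                duration_col=duration_col,
                event_col=event_col,
                strata=strata_cols or None,
                fit_options={"step_size": 0.5},
            )
        except Exception as err:
            raise RuntimeError(f"Cox fit failed to converge: {err}") from err
        summary = cph.summary.loc["treatment"]
        coef = float(summary["coef"])
        with np.errstate(over="ignore"):
            lo = float(np.exp(summary["coef lower 95%"]))
            hi = float(np.exp(summary["coef upper 95%"]))
        p = float(summary["p"])
    elif ties == "breslow":
        from statsmodels.duration.hazard_regression import PHReg

        exog_cols = [c for c in design.columns if c not in (duration_col, event_col)]
        strata_codes = (
            records[strata_cols].astype(str).agg("|".join, axis=1).to_numpy()
            if strata_cols
            else None
        )
        try:
            model = PHReg(
                design[duration_col].to_numpy(),
                design[exog_cols].to_numpy(float),
                status=design[event_col].to_numpy(),
                strata=strata_codes,
                ties="breslow",
            )
            res = model.fit()
        except Exception as err:
            raise RuntimeError(f"Cox fit failed to converge: {err}") from err
        k = exog_cols.index("treatment")
        coef = float(res.params[k])
        se = float(res.bse[k])
        z = stats.norm.ppf(0.975)
        lo, hi = float(np.exp(coef - z * se)), float(np.exp(coef + z * se))
        p = float(res.pvalues[k])
    else:
        raise ValueError(f"unknown tie method {ties!r}")
    return CoxResult(
        hr=float(np.exp(coef)),
        ci_lower=lo,
        ci_upper=hi,
        p_value=p,
        n=len(records),
        n_events=int(records[event_col].sum()),
        model={
            "strata": strata_cols,
            "covariates": list(covariates),
            "interactions": [f"{a}:{b}" for a, b in interactions],
            "ties": ties,
        },
    )


def subgroup_forest_table(
    records: pd.DataFrame,
    duration_col: str,
    event_col: str,
    treatment_col: str,
    treated_label: str,
    subgroup_cols: Sequence[str],
    min_events: int = 5,
) -> pd.DataFrame:
    """Univariate treatment Cox fit per level of each subgroup column.

    Levels with fewer than ``min_events`` events, a single arm, or a failed
    fit are reported as not evaluable rather than raising.
    """
    rows = []
    for col in subgroup_cols:
        for level in pd.unique(records[col].dropna()):
            sub = records[records[col] == level]
            n_events = int(sub[event_col].sum())
            row = {
                "subgroup": col,
                "level": level,
                "n": len(sub),
                "n_events": n_events,
                "hr": np.nan,
                "ci_lower": np.nan,
                "ci_upper": np.nan,
                "p_value": np.nan,
                "evaluable": False,
            }
            if n_events >= min_events and sub[treatment_col].nunique() == 2:
                try:
                    res = cox_fit(
                        sub, duration_col, event_col, treatment_col, treated_label
                    )
                    row.update(
                        hr=res.hr,
                        ci_lower=res.ci_lower,
                        ci_upper=res.ci_upper,
                        p_value=res.p_value,
                        evaluable=True,
                    )
                except (RuntimeError, ValueError):
                    pass
            rows.append(row)
    return pd.DataFrame(rows)


def rank_sum_test(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U with exact two-sided p for small tie-free samples and
    the tie-corrected normal approximation otherwise (scipy's auto rule)."""
    a, b = np.asarray(values_a, float), np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def response_table(
    records: pd.DataFrame,
    group_cols: Sequence[str] = ("subtype",),
    arm_col: str = "arm",
    arms: Sequence[str] = ("abemaciclib", "erlotinib"),
) -> pd.DataFrame:
    """Per-group×arm BOR breakdown with ORR/DCR and chi-square arm contrasts
    (a published-style response table)."""
    rows = []
    groups = [("all", records)] + [
        (str(level), records[records[group_cols[0]] == level])
        for level in pd.unique(records[group_cols[0]])
    ]
    for name, sub in groups:
        per_arm = {}
        for arm in arms:
            arm_records = sub[sub[arm_col] == arm]
            if len(arm_records) == 0:
                continue
            rates = compute_response_rates(arm_records["bor"])
            counts = arm_records["bor"].value_counts()
            per_arm[arm] = (rates, counts, len(arm_records))
        for arm, (rates, counts, n) in per_arm.items():
            row = {
                "group": name,
                "arm": arm,
                "n": n,
                "orr_n": rates.orr.responders,
                "orr_pct": round(rates.orr.rate_percent, 1),
                "dcr_n": rates.dcr.responders,
                "dcr_pct": round(rates.dcr.rate_percent, 1),
            }
            for cat in BOR_CATEGORIES:
                row[f"bor_{cat}"] = int(counts.get(cat, 0))
            rows.append(row)
        if len(per_arm) == 2:
            (r_a, _, n_a), (r_b, _, n_b) = (per_arm[a] for a in arms)
            for label, ra, rb in (
                ("orr", r_a.orr, r_b.orr),
                ("dcr", r_a.dcr, r_b.dcr),
            ):
                table = np.array(
                    [
                        [ra.responders, n_a - ra.responders],
                        [rb.responders, n_b - rb.responders],
                    ]
                )
                try:
                    _, p = chi_square_2x2(table)
                except ValueError:
                    p = np.nan
                for row in rows[-2:]:
                    row[f"{label}_p_chi2"] = p
    return pd.DataFrame(rows)
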