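"""Response-rate and survival statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from krassubtype.efficacy import (
    chi_square_2x2,
    compute_response_rates,
    cox_fit,
    km_fit,
    logrank_test,
    rank_sum_test,
    response_table,
    stratified_logistic_lrt,
    subgroup_forest_table,
)
from krassubtype.synthetic import CohortSpec, simulate_survival_cohort


def _bor(cr=0, pr=0, sd=0, pd_=0, ne=0):
    return ["CR"] * cr + ["PR"] * pr + ["SD"] * sd + ["PD"] * pd_ + ["NE"] * ne


class TestResponseRates:
    def test_published_kl_treated_arm_arithmetic(self):
        r = compute_response_rates(_bor(pr=2, sd=20, pd_=1, ne=1))
        assert round(r.dcr.rate_percent, 1) == 91.7
        assert round(r.orr.rate_percent, 1) == 8.3

    def test_published_tr_treated_arm_by_independent_count(self):
        bor = _bor(pr=9, sd=43, pd_=18, ne=9)  # n=79
        r = compute_response_rates(bor)
        n_resp = sum(1 for b in bor if b in ("CR", "PR"))
        n_ctrl = sum(1 for b in bor if b in ("CR", "PR", "SD"))
        assert r.orr.responders == n_resp and r.dcr.responders == n_ctrl
        assert round(r.orr.rate_percent, 1) == 11.4
        assert round(r.dcr.rate_percent, 1) == 65.8

    def test_all_progressors_give_zero_rates(self):
        r = compute_response_rates(_bor(pd_=10))
        assert r.orr.rate_percent == 0 and r.dcr.rate_percent == 0

    def test_orr_never_exceeds_dcr(self, rng):
        for _ in range(20):
            bor = rng.choice(["CR", "PR", "SD", "PD", "NE"], size=rng.integers(1, 40))
            r = compute_response_rates(bor)
            assert r.orr.rate_percent <= r.dcr.rate_percent

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            compute_response_rates([])


class TestChiSquare:
    def test_closed_form_value(self):
        # n(ad-bc)^2 / (r1 r2 c1 c2)
        stat, _ = chi_square_2x2([[22, 2], [8, 15]])
        expected = 47 * (22 * 15 - 2 * 8) ** 2 / (24 * 23 * 30 * 17)
        assert stat == pytest.approx(expected)
        assert stat == pytest.approx(16.46, abs=0.01)

    def test_identical_proportions_give_zero(self):
        stat, p = chi_square_2x2([[10, 20], [5, 10]])
        assert stat == pytest.approx(0) and p == pytest.approx(1)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 5]])


class TestLogisticLRT:
    @staticmethod
    def _records(rng, n, p_treat=0.4, p_control=0.4):
        arm = np.where(rng.random(n) < 0.5, "abemaciclib", "erlotinib")
        p = np.where(arm == "abemaciclib", p_treat, p_control)
        bor = np.where(rng.random(n) < p, "SD", "PD")
        return pd.DataFrame(
            {"arm": arm, "bor": bor,
             "sex": rng.choice(["male", "female"], n),
             "ecog_ps": rng.integers(0, 2, n)}
        )

    def test_null_distribution_of_statistic(self):
        rng = np.random.default_rng(0)
        pvals, stats_ = [], []
        for _ in range(200):
            rec = self._records(rng, 400)
            p, _or = stratified_logistic_lrt(rec, "dcr", strata=())
            pvals.append(p)
            stats_.append(stats.chi2.ppf(1 - p, 1))
        # LRT statistic ~ chi2(1) under the null: mean 1, uniform p
        assert np.mean(stats_) == pytest.approx(1.0, abs=0.3)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_unstratified_matches_independent_likelihood_fit(self):
        rng = np.random.default_rng(1)
        rec = self._records(rng, 300, p_treat=0.6, p_control=0.35)
        p, odds = stratified_logistic_lrt(rec, "dcr", strata=())
        # independent two-model fit via direct Bernoulli likelihoods
        y = rec["bor"].isin({"CR", "PR", "SD"}).to_numpy(float)
        t = (rec["arm"] == "abemaciclib").to_numpy(float)
        p1, p0 = y[t == 1].mean(), y[t == 0].mean()
        ll_full = (
            (y[t == 1] * np.log(p1) + (1 - y[t == 1]) * np.log(1 - p1)).sum()
            + (y[t == 0] * np.log(p0) + (1 - y[t == 0]) * np.log(1 - p0)).sum()
        )
        pbar = y.mean()
        ll_reduced = (y * np.log(pbar) + (1 - y) * np.log(1 - pbar)).sum()
        lrt = 2 * (ll_full - ll_reduced)
        assert p == pytest.approx(stats.chi2.sf(lrt, 1), rel=1e-6)
        assert odds == pytest.approx((p1 / (1 - p1)) / (p0 / (1 - p0)), rel=1e-4)

    def test_stratified_p_differs_but_is_valid(self):
        rng = np.random.default_rng(2)
        rec = self._records(rng, 300, p_treat=0.6, p_control=0.35)
        p, _ = stratified_logistic_lrt(rec, "dcr", strata=("sex", "ecog_ps"))
        assert 0 <= p <= 1

    def test_constant_outcome_raises(self):
        rec = pd.DataFrame({"arm": ["abemaciclib", "erlotinib"] * 5, "bor": ["PD"] * 10})
        with pytest.raises(ValueError, match="constant"):
            stratified_logistic_lrt(rec, "orr")


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        fit = km_fit([1, 2, 3], [1, 1, 1])
        assert np.allclose(fit.survival, [2 / 3, 1 / 3, 0])
        assert fit.median == 2

    def test_all_censored_median_not_reached(self):
        fit = km_fit([5, 6, 7], [0, 0, 0])
        assert fit.median is None and fit.n_events == 0

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(5, 200)
        fit = km_fit(t, np.ones_like(t, int))
        emp = np.array([(t > u).mean() for u in fit.times])
        assert np.allclose(fit.survival, emp)

    def test_matches_lifelines_estimator(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(10, 150)
        e = (rng.random(150) < 0.7).astype(int)
        fit = km_fit(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ours = pd.Series(fit.survival, index=fit.times)
        theirs = kmf.survival_function_["KM_estimate"].reindex(ours.index)
        assert np.allclose(ours.values, theirs.values)
        assert fit.median == pytest.approx(kmf.median_survival_time_)

    def test_large_sample_median_matches_closed_form(self, rng):
        m = 13.05
        t = rng.exponential(m / np.log(2), 100_000)
        fit = km_fit(t, np.ones_like(t, int))
        assert fit.median == pytest.approx(m, rel=0.02)

    def test_median_ci_covers_true_median(self, rng):
        m, covered = 8.0, 0
        n_rep = 300
        for _ in range(n_rep):
            t = rng.exponential(m / np.log(2), 60)
            c = rng.uniform(0, 40, 60)
            fit = km_fit(np.minimum(t, c), (t <= c).astype(int))
            lo, hi = fit.median_ci
            if (lo is None or lo <= m) and (hi is None or m <= hi):
                covered += 1
        assert 0.90 <= covered / n_rep <= 0.995

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            km_fit([], [])


class TestLogRank:
    def test_identical_groups_give_zero(self):
        t, e = [1, 2, 3, 4], [1, 1, 0, 1]
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0) and p == pytest.approx(1)

    def test_matches_hand_tallied_risk_sets(self):
        ta, ea = np.array([1.0, 3.0, 5.0]), np.array([1, 1, 1])
        tb, eb = np.array([2.0, 4.0, 6.0]), np.array([1, 0, 1])
        stat, _ = logrank_test(ta, ea, tb, eb)
        # independent risk-set tally
        t = np.r_[ta, tb]
        e = np.r_[ea, eb]
        grp = np.r_[np.zeros(3), np.ones(3)]
        O = E = V = 0.0
        for u in np.unique(t[e == 1]):
            at_risk = t >= u
            n, n1 = at_risk.sum(), (at_risk & (grp == 0)).sum()
            d = ((t == u) & (e == 1)).sum()
            d1 = ((t == u) & (e == 1) & (grp == 0)).sum()
            O += d1
            E += d * n1 / n
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / max(n - 1, 1)
        assert stat == pytest.approx((O - E) ** 2 / V)

    def test_power_at_strong_effect_and_trial_cell_sizes(self):
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(200):
            ta = rng.exponential(4 / 0.25 / np.log(2), 24)
            tb = rng.exponential(4 / np.log(2), 23)
            _, p = logrank_test(ta, np.ones(24, int), tb, np.ones(23, int))
            pvals.append(p)
        assert np.median(pvals) < 0.05

    def test_zero_events_raise(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [0, 0], [3, 4], [0, 0])


class TestCox:
    def test_two_pair_fit_matches_partial_likelihood_grid(self):
        df = pd.DataFrame(
            {"months": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 1, 1],
             "treated": [1.0, 0.0, 1.0, 0.0]}
        )
        res = cox_fit(df, "months", "event", "treated")

        def neg_log_pl(beta):
            risk = np.exp(beta * df["treated"].to_numpy())
            ll = 0.0
            order = np.argsort(df["months"].to_numpy())
            remaining = list(order)
            for i in order:
                ll += beta * df["treated"].iloc[i] - np.log(risk[remaining].sum())
                remaining.remove(i)
            return -ll

        opt = minimize_scalar(neg_log_pl, bounds=(-5, 5), method="bounded")
        assert np.log(res.hr) == pytest.approx(opt.x, abs=1e-3)

    def test_label_swap_gives_reciprocal_hr(self, rng):
        t = rng.exponential(5, 80)
        arm = (rng.random(80) < 0.5).astype(float)
        t[arm == 1] *= 2
        df = pd.DataFrame({"months": t, "event": 1, "treated": arm})
        res = cox_fit(df, "months", "event", "treated")
        df2 = df.assign(treated=1 - df["treated"])
        res2 = cox_fit(df2, "months", "event", "treated")
        assert res.hr == pytest.approx(1 / res2.hr, rel=1e-6)

    def test_null_estimate_near_one_with_ci_coverage(self):
        spec = CohortSpec(
            n_per_cell={("KL", "abemaciclib"): 2000, ("KL", "erlotinib"): 2000},
            median_survival_months={
                "os": {("KL", "abemaciclib"): 8.0, ("KL", "erlotinib"): 8.0},
                "pfs": {("KL", "abemaciclib"): 4.0, ("KL", "erlotinib"): 4.0},
            },
            censor_rate={"os": 0.25, "pfs": 0.1},
            seed=5,
        )
        clin = simulate_survival_cohort(spec, enforce_pfs_le_os=False)
        res = cox_fit(clin, "os_months", "os_event", "arm", treated_label="abemaciclib")
        assert res.hr == pytest.approx(1.0, abs=0.12)
        assert res.ci_lower <= 1.0 <= res.ci_upper

    def test_multivariable_with_no_terms_equals_univariate(self, rng):
        t = rng.exponential(6, 60)
        arm = (rng.random(60) < 0.5).astype(float)
        df = pd.DataFrame({"months": t, "event": (rng.random(60) < 0.8).astype(int),
                           "treated": arm})
        a = cox_fit(df, "months", "event", "treated")
        b = cox_fit(df, "months", "event", "treated", strata=(), covariates=())
        assert a.hr == b.hr and a.p_value == b.p_value

    def test_breslow_ties_close_to_efron_without_ties(self, rng):
        t = rng.exponential(6, 100)
        arm = (rng.random(100) < 0.5).astype(float)
        t[arm == 1] *= 1.5
        df = pd.DataFrame({"months": t, "event": 1, "treated": arm})
        efron = cox_fit(df, "months", "event", "treated", ties="efron")
        breslow = cox_fit(df, "months", "event", "treated", ties="breslow")
        # identical when there are no tied event times
        assert efron.hr == pytest.approx(breslow.hr, rel=1e-4)

    def test_no_events_raise(self):
        df = pd.DataFrame({"months": [1, 2], "event": [0, 0], "treated": [0.0, 1.0]})
        with pytest.raises(ValueError):
            cox_fit(df, "months", "event", "treated")


class TestSubgroupForest:
    @staticmethod
    def _cohort(rng, n=300):
        arm = np.where(rng.random(n) < 0.5, "abemaciclib", "erlotinib")
        sex = rng.choice(["male", "female"], n)
        hr_true = np.where(sex == "male", 0.4, 0.9)
        lam = np.log(2) / 6 * np.where(arm == "abemaciclib", hr_true, 1.0)
        t = rng.exponential(1 / lam)
        return pd.DataFrame(
            {"arm": arm, "sex": sex, "os_months": t, "os_event": 1,
             "all": "cohort"}
        )

    def test_two_subgroups_recover_distinct_hazard_ratios(self):
        rng = np.random.default_rng(7)
        rec = self._cohort(rng, n=3000)
        table = subgroup_forest_table(rec, "os_months", "os_event", "arm",
                                      "abemaciclib", ["sex"])
        by_level = table.set_index("level")
        assert by_level.loc["male", "hr"] == pytest.approx(0.4, rel=0.15)
        assert by_level.loc["female", "hr"] == pytest.approx(0.9, rel=0.15)

    def test_small_subgroup_marked_not_evaluable(self, rng):
        rec = self._cohort(rng, n=40)
        rec.loc[rec.index[:36], "sex"] = "male"  # 4 female -> < 5 events
        table = subgroup_forest_table(rec, "os_months", "os_event", "arm",
                                      "abemaciclib", ["sex"])
        female = table[table.level == "female"].iloc[0]
        assert not female.evaluable and np.isnan(female.hr)

    def test_full_cohort_subgroup_equals_overall_fit(self, rng):
        rec = self._cohort(rng, n=200)
        table = subgroup_forest_table(rec, "os_months", "os_event", "arm",
                                      "abemaciclib", ["all"])
        overall = cox_fit(rec, "os_months", "os_event", "arm", treated_label="abemaciclib")
        row = table.iloc[0]
        assert row.hr == overall.hr and row.p_value == overall.p_value


class TestRankSum:
    def test_exact_enumeration_small_sample(self):
        u, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert u == 0 and p == pytest.approx(0.1)  # 2/C(6,3)

    def test_identical_groups(self):
        _, p = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_power_at_cell_line_scale(self):
        # 9 vs 15 groups from shifted lognormals (sensitivity-contrast design)
        rng = np.random.default_rng(11)
        reject_alt = np.mean(
            [rank_sum_test(rng.lognormal(0, 1, 9), rng.lognormal(1.2, 1, 15))[1] < 0.05
             for _ in range(200)]
        )
        reject_null = np.mean(
            [rank_sum_test(rng.lognormal(0, 1, 9), rng.lognormal(0, 1, 15))[1] < 0.05
             for _ in range(200)]
        )
        assert reject_alt > reject_null
        assert reject_alt > 0.5

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestResponseTable:
    def test_counts_partition_and_rates_consistent(self, trial_cohort):
        clin = trial_cohort.clinical
        table = response_table(clin)
        for _, row in table.iterrows():
            total = sum(row[f"bor_{c}"] for c in ("CR", "PR", "SD", "PD", "NE"))
            assert total == row.n
            assert row.orr_pct <= row.dcr_pct
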