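import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from tpsad import (
    CohortSimParams,
    SurvivalData,
    ValidationError,
    cox_fit,
    cox_score_test,
    group_compare,
    km_curve,
    logrank_test,
    quintile_strata,
    simulate_cohort,
)
from tpsad.pipeline import fit_recurrence_cox


def breslow_loglik_direct(beta, times, events, x):
    """Written-out Breslow partial likelihood, evaluated by direct loops.

    Independent oracle: no shared code with the fitting path.
    """
    ll = 0.0
    for i in range(len(times)):
        if not events[i]:
            continue
        risk = [j for j in range(len(times)) if times[j] >= times[i]]
        denom = sum(math.exp(beta * x[j]) for j in risk)
        ll += beta * x[i] - math.log(denom)
    return ll


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        curve = km_curve(SurvivalData(np.array([1.0, 2.0, 3.0]), np.zeros(3, bool)))
        assert curve.survival_at(10.0) == 1.0
        assert curve.event_times.size == 0

    def test_product_limit_by_hand(self):
        data = SurvivalData(np.array([1.0, 2.0, 3.0]), np.array([True, True, False]))
        curve = km_curve(data)
        assert curve.survival_at(1.5) == pytest.approx(2 / 3)
        assert curve.survival_at(2.5) == pytest.approx(1 / 3)
        assert curve.survival_at(0.5) == 1.0
        np.testing.assert_array_equal(curve.at_risk, [3, 2])

    def test_all_events_steps_of_one_over_n(self, rng):
        times = rng.permutation(np.arange(1.0, 9.0))
        curve = km_curve(SurvivalData(times, np.ones(8, bool)))
        np.testing.assert_allclose(curve.survival, 1 - np.arange(1, 9) / 8)

    def test_equals_one_minus_ecdf_without_censoring(self, rng):
        times = rng.exponential(10, size=60)
        curve = km_curve(SurvivalData(times, np.ones(60, bool)))
        for t in [1.0, 5.0, 12.0]:
            assert curve.survival_at(t) == pytest.approx(np.mean(times > t))

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        times = rng.exponential(10, size=80)
        events = rng.random(80) < 0.7
        curve = km_curve(SurvivalData(times, events))
        kmf = KaplanMeierFitter().fit(times, events)
        for t in [2.0, 8.0, 20.0]:
            assert curve.survival_at(t) == pytest.approx(
                float(kmf.predict(t)), rel=1e-9
            )

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            SurvivalData(np.array([-1.0]), np.array([True]))


class TestLogrank:
    def test_identical_groups_near_zero(self):
        times = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        events = np.ones(8, bool)
        # tie-for-tie identical groups: observed equals expected
        chi2, df, p = logrank_test(SurvivalData(times, events), [0, 0, 0, 0, 1, 1, 1, 1])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1

    def test_exhaustive_permutation_oracle_small_n(self):
        """Asymptotic p agrees with the exact label-permutation distribution
        (the permutation p is granular in steps of 1/70 at n=8, 4 vs 4)."""
        times = np.array([15.7, 1.8, 25.3, 1.4, 9.2, 16.6, 9.5, 58.8])
        events = np.array([1, 1, 1, 1, 1, 0, 1, 1], bool)
        groups = np.array([1, 1, 0, 0, 0, 1, 1, 0])
        data = SurvivalData(times, events)
        chi2_obs, _, p_asym = logrank_test(data, groups)

        chi2_perm = []
        for pos in itertools.combinations(range(8), 4):
            labels = np.isin(np.arange(8), pos).astype(int)
            chi2_perm.append(logrank_test(data, labels)[0])
        p_perm = np.mean(np.asarray(chi2_perm) >= chi2_obs - 1e-12)
        assert abs(p_asym - p_perm) < 0.02

    def test_separated_groups_significant(self, rng):
        early = rng.exponential(1.0, size=100)
        late = rng.exponential(10.0, size=100)
        times = np.concatenate([early, late])
        events = np.ones(200, bool)
        groups = np.repeat([0, 1], 100)
        chi2, _, p = logrank_test(SurvivalData(times, events), groups)
        assert p < 1e-3

    def test_matches_lifelines_multigroup(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        times = rng.exponential(5, size=90)
        events = rng.random(90) < 0.8
        groups = rng.integers(0, 3, size=90)
        chi2, df, p = logrank_test(SurvivalData(times, events), groups)
        ref = multivariate_logrank_test(times, groups, events)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-8)
        assert p == pytest.approx(ref.p_value, rel=1e-8)

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test(SurvivalData(np.ones(3), np.ones(3, bool)), [0, 0, 0])


class TestCoxFit:
    def test_brute_force_partial_likelihood_oracle(self):
        """Newton estimate matches direct numerical maximization on n=8."""
        times = np.array([3.0, 5.0, 7.0, 2.0, 12.0, 9.0, 4.0, 8.0])
        events = np.array([1, 1, 0, 1, 1, 0, 1, 1], bool)
        x = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 0.0])
        data = SurvivalData(times, events, pd.DataFrame({"x": x}))
        fit = cox_fit(data)
        assert fit.converged

        grid = optimize.minimize_scalar(
            lambda b: -breslow_loglik_direct(b, times, events, x),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        )
        assert abs(fit.coef["x"] - grid.x) < 1e-3
        assert fit.log_likelihood == pytest.approx(-grid.fun, abs=1e-8)

    def test_null_covariate_near_zero(self, rng):
        n = 2000
        times = rng.exponential(10, size=n)
        events = rng.random(n) < 0.7
        x = rng.random(n) < 0.5  # independent of outcome
        fit = cox_fit(SurvivalData(times, events, pd.DataFrame({"x": x.astype(float)})))
        assert abs(fit.coef["x"]) < 3 * fit.se["x"]
        assert fit.hr["x"] == pytest.approx(1.0, abs=0.2)

    def test_exponential_two_group_rate_ratio_oracle(self, rng):
        """Without censoring, beta-hat approaches the log event-rate ratio."""
        n = 600
        lam0, lam1 = 0.05, 0.15
        x = np.repeat([0.0, 1.0], n // 2)
        times = np.where(
            x == 1, rng.exponential(1 / lam1, n), rng.exponential(1 / lam0, n)
        )
        events = np.ones(n, bool)
        fit = cox_fit(SurvivalData(times, events, pd.DataFrame({"x": x})))
        rate0 = (n / 2) / times[x == 0].sum()
        rate1 = (n / 2) / times[x == 1].sum()
        assert fit.coef["x"] == pytest.approx(math.log(rate1 / rate0), abs=0.15)

    def test_matches_lifelines_breslow(self, small_cohort):
        from lifelines import CoxPHFitter

        fit = fit_recurrence_cox(small_cohort)
        df = pd.DataFrame(
            {
                "epe": small_cohort["epe"].astype(float),
                "svi": small_cohort["svi"].astype(float),
                "positive_margins": small_cohort["positive_margins"].astype(float),
                "grade_intermediate": (small_cohort["grade_group"] == "intermediate").astype(float),
                "grade_high": (small_cohort["grade_group"] == "high").astype(float),
                "T": small_cohort["followup_time"],
                "E": small_cohort["recurrence"].astype(int),
            }
        )
        cph = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(
            fit.coef.to_numpy(), cph.params_[fit.coef.index].to_numpy(), atol=1e-4
        )
        np.testing.assert_allclose(
            fit.se.to_numpy(), cph.standard_errors_[fit.coef.index].to_numpy(), atol=1e-4
        )

    def test_ci_brackets_hr(self, small_cohort):
        fit = fit_recurrence_cox(small_cohort)
        assert (fit.ci_low < fit.hr).all() and (fit.hr < fit.ci_high).all()
        np.testing.assert_allclose(fit.hr, np.exp(fit.coef), rtol=1e-12)

    def test_score_test_equals_logrank_without_ties(self, rng):
        times = rng.exponential(5, size=50)  # continuous -> untied
        events = rng.random(50) < 0.8
        x = (rng.random(50) < 0.5).astype(float)
        data = SurvivalData(times, events, pd.DataFrame({"x": x}))
        chi2_score, _ = cox_score_test(data, "x")
        chi2_lr, _, _ = logrank_test(data, x)
        assert abs(chi2_score - chi2_lr) < 1e-6

    def test_perfect_separation_flagged(self):
        times = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        events = np.ones(6, bool)
        x = np.array([1.0, 1, 1, 0, 0, 0])  # all early events in one group
        fit = cox_fit(SurvivalData(times, events, pd.DataFrame({"x": x})))
        assert not fit.converged

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError):
            cox_fit(
                SurvivalData(
                    np.arange(1.0, 7.0), np.ones(6, bool), pd.DataFrame({"x": np.ones(6)})
                )
            )

    def test_planted_hazard_recovery_coverage(self):
        """|beta-hat - beta| < 2 SE for >= 93% of seeded replicate cohorts."""
        params = CohortSimParams(n_patients=2500)
        truth = {
            "epe": params.log_hr_epe,
            "svi": params.log_hr_svi,
            "positive_margins": params.log_hr_margins,
            "grade_intermediate": params.log_hr_grade_intermediate,
            "grade_high": params.log_hr_grade_high,
        }
        hits = {k: 0 for k in truth}
        n_rep = 100
        for seed in range(n_rep):
            fit = fit_recurrence_cox(simulate_cohort(params, seed=seed))
            assert fit.converged
            for name, beta in truth.items():
                if abs(fit.coef[name] - beta) < 2 * fit.se[name]:
                    hits[name] += 1
        for name, n_hit in hits.items():
            assert n_hit >= 0.93 * n_rep, (name, n_hit)


class TestQuintiles:
    def test_uniform_spacing(self):
        labels = quintile_strata(np.arange(1.0, 11.0))
        np.testing.assert_array_equal(labels, [1, 1, 2, 2, 3, 3, 4, 4, 5, 5])

    def test_ties_go_to_lower_stratum(self):
        values = np.array([1.0, 1, 1, 1, 2, 3, 4, 5, 6, 7])
        labels = quintile_strata(values)
        # the 20th-percentile cut falls on the tied value 1 -> all go low
        assert set(labels[values == 1.0]) == {1}

    def test_degenerate_single_stratum(self):
        with pytest.warns(UserWarning):
            labels = quintile_strata(np.full(10, 3.0))
        assert set(labels) == {1}

    def test_balanced_sizes_on_continuous_draws(self, rng):
        labels = quintile_strata(rng.standard_normal(1000))
        counts = np.bincount(labels)[1:]
        np.testing.assert_array_equal(counts, [200] * 5)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValidationError):
            quintile_strata([1.0, 2.0, 3.0])


class TestGroupCompare:
    def test_identical_groups_null(self):
        v = np.array([1.0, 2, 3, 1, 2, 3])
        stat, p = group_compare(v, [0, 0, 0, 1, 1, 1])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_textbook_two_sample_t(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 6.0])
        stat, p = group_compare(np.concatenate([a, b]), [0, 0, 0, 1, 1, 1])
        sp2 = (a.var(ddof=1) + b.var(ddof=1)) / 2  # equal n pooled variance
        expected_t = (a.mean() - b.mean()) / math.sqrt(sp2 * (2 / 3))
        assert stat == pytest.approx(expected_t, rel=1e-12)

    def test_three_groups_use_anova(self, rng):
        v = rng.normal(size=90)
        g = np.repeat([0, 1, 2], 30)
        stat, p = group_compare(v, g)
        from scipy.stats import f_oneway

        ref = f_oneway(v[g == 0], v[g == 1], v[g == 2])
        assert stat == pytest.approx(ref.statistic)

    def test_anova_null_p_uniform(self):
        rng = np.random.default_rng(77)
        pvals = []
        for _ in range(200):
            v = rng.normal(size=30)
            pvals.append(group_compare(v, np.repeat([0, 1, 2], 10))[1])
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            group_compare([1.0, 2.0, 3.0], [0, 0, 1])
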