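import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import recurpred as rp
from recurpred.survival import (
    cox_partial_loglik,
    cox_univariate,
    dfs_at,
    evaluate_cohort,
    km_estimate,
    logrank,
    roc,
    sens_spec,
)

from oracles import empirical_survival, grid_cox_beta, naive_auc, naive_cox_loglik


class TestKaplanMeier:
    def test_all_censored_survival_stays_at_one(self):
        curve = km_estimate([5.0, 8.0, 12.0], [0, 0, 0])
        assert curve.event_times.size == 0
        assert curve.survival_at(100.0) == 1.0

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(20.0, 40)
        curve = km_estimate(times, np.ones(40, int))
        for t in [0.0, 5.0, 10.0, 30.0, 80.0]:
            assert curve.survival_at(t) == pytest.approx(
                empirical_survival(times, t), abs=1e-12)

    def test_textbook_six_subject_product_limit(self):
        # events at 7, 15, 25; censored at 6, 10, 19
        curve = km_estimate([7, 15, 25, 6, 10, 19], [1, 1, 1, 0, 0, 0])
        np.testing.assert_array_equal(curve.event_times, [7, 15, 25])
        np.testing.assert_allclose(curve.survival, [4 / 5, 8 / 15, 0.0], atol=1e-12)
        np.testing.assert_array_equal(curve.n_risk, [5, 3, 1])
        # Greenwood at t=7: S^2 * d/(n(n-d)) = 0.64 * 1/20
        assert curve.variance[0] == pytest.approx(0.64 / 20, abs=1e-12)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0, 2.0], [1, 1])

    @given(st.lists(st.tuples(st.floats(0.1, 100.0), st.booleans()),
                    min_size=1, max_size=30))
    @settings(max_examples=50, derandomize=True)
    def test_survival_is_monotone_nonincreasing_from_one(self, records):
        times = [t for t, _ in records]
        events = [int(e) for _, e in records]
        curve = km_estimate(times, events)
        surv = np.concatenate([[1.0], curve.survival])
        assert (np.diff(surv) <= 1e-12).all()

    def test_dfs_at_before_first_event_is_one(self):
        curve = km_estimate([50.0, 70.0], [1, 1])
        assert dfs_at(curve, horizon=30.0) == 1.0

    def test_five_year_dfs_reads_curve_at_sixty_months(self):
        curve = km_estimate([12, 24, 59, 80, 90], [1, 1, 1, 0, 0])
        assert dfs_at(curve) == curve.survival_at(60.0) == pytest.approx(
            (4 / 5) * (3 / 4) * (2 / 3))


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        times = [3.0, 5.0, 9.0, 11.0] * 2
        events = [1, 0, 1, 1] * 2
        groups = [0] * 4 + [1] * 4
        res = logrank(times, events, groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_agrees_with_lifelines_on_random_data(self, rng):
        from lifelines.statistics import logrank_test

        for _ in range(20):
            n = int(rng.integers(20, 60))
            times = rng.exponential(10.0, n)
            events = (rng.random(n) < 0.7).astype(int)
            groups = rng.random(n) < 0.5
            if groups.all() or not groups.any() or events.sum() == 0:
                continue
            ours = logrank(times, events, groups)
            ref = logrank_test(times[groups], times[~groups],
                               events[groups], events[~groups])
            assert ours.statistic == pytest.approx(ref.test_statistic, abs=1e-8)
            assert ours.p_value == pytest.approx(ref.p_value, abs=1e-8)

    def test_zero_events_flagged_undefined(self):
        with pytest.warns(UserWarning):
            res = logrank([1.0, 2.0], [0, 0], [0, 1])
        assert np.isnan(res.statistic) and res.n_events == 0


class TestCox:
    def test_identical_groups_give_unit_hazard_ratio(self):
        times = [2.0, 4.0, 6.0, 8.0] * 2
        events = [1, 1, 0, 1] * 2
        groups = [0] * 4 + [1] * 4
        fit = cox_univariate(times, events, groups)
        assert fit.beta == pytest.approx(0.0, abs=1e-8)
        assert fit.hr == pytest.approx(1.0, abs=1e-8)
        assert fit.ci_low <= fit.hr <= fit.ci_high

    def test_newton_raphson_matches_grid_search_on_tiny_data(self, rng):
        """On every random n<=10 dataset the NR optimum equals a brute-force
        grid maximizer of an independently coded partial likelihood."""
        checked = 0
        while checked < 12:
            n = int(rng.integers(6, 11))
            times = np.round(rng.exponential(10.0, n), 2)
            events = (rng.random(n) < 0.8).astype(int)
            groups = rng.random(n) < 0.5
            if groups.all() or not groups.any() or events.sum() == 0:
                continue
            e1 = events[groups].sum()
            if e1 == 0 or e1 == events.sum():
                continue  # monotone likelihood: flagged, not a number
            fit = cox_univariate(times, events, groups)
            if abs(fit.beta) > 4.5:
                continue  # outside the oracle grid
            assert fit.beta == pytest.approx(
                grid_cox_beta(times, events, groups), abs=1e-4)
            checked += 1

    def test_partial_loglik_matches_naive_implementation(self, rng):
        times = rng.exponential(5.0, 15)
        events = (rng.random(15) < 0.7).astype(int)
        groups = rng.random(15) < 0.5
        for beta in (-1.0, 0.0, 0.7):
            assert cox_partial_loglik(beta, times, events, groups) == pytest.approx(
                naive_cox_loglik(beta, times, events, list(groups.astype(int))),
                abs=1e-10)

    def test_agrees_with_lifelines_without_ties(self, rng):
        from lifelines import CoxPHFitter

        n = 80
        times = rng.exponential(10.0, n)  # continuous: no ties, Breslow==Efron
        groups = rng.random(n) < 0.5
        events = (rng.random(n) < 0.7).astype(int)
        fit = cox_univariate(times, events, groups)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": times, "e": events, "x": groups.astype(int)}),
            duration_col="t", event_col="e")
        assert fit.beta == pytest.approx(cph.params_["x"], abs=1e-6)
        assert fit.se == pytest.approx(cph.standard_errors_["x"], abs=1e-6)

    def test_efron_and_breslow_coincide_without_ties(self, rng):
        times = rng.exponential(10.0, 30)
        events = (rng.random(30) < 0.6).astype(int)
        groups = rng.random(30) < 0.5
        b = cox_univariate(times, events, groups, ties="breslow")
        e = cox_univariate(times, events, groups, ties="efron")
        assert b.beta == pytest.approx(e.beta, abs=1e-8)

    def test_all_events_in_one_group_reports_infinite_flag(self):
        times = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
        events = [1, 1, 1, 0, 0, 0]
        groups = [1, 1, 1, 0, 0, 0]
        fit = cox_univariate(times, events, groups)
        assert fit.infinite and fit.hr == np.inf

    def test_simulated_hazard_ratio_recovery(self, rng):
        """Exponential simulation, true HR 4.5: the estimate covers the truth
        in nearly all replicates."""
        cover = 0
        reps = 20
        for _ in range(reps):
            n = 400
            groups = rng.random(n) < 0.5
            lam = 0.004 * np.where(groups, 4.5, 1.0)
            times = rng.exponential(1.0 / lam)
            censor = rng.uniform(50, 300, n)
            events = (times <= censor).astype(int)
            obs = np.minimum(times, censor)
            fit = cox_univariate(obs, events, groups)
            cover += fit.ci_low <= 4.5 <= fit.ci_high
        assert cover >= int(0.85 * reps)


class TestROC:
    def test_perfect_separation_gives_auc_one(self):
        res = roc([0.9, 0.8, 0.7, -0.5, -0.6], [1, 1, 1, 0, 0])
        assert res.auc == 1.0

    def test_identical_scores_give_half(self):
        res = roc([0.3] * 6, [1, 1, 1, 0, 0, 0])
        assert res.auc == pytest.approx(0.5)

    def test_trapezoid_auc_equals_pairwise_concordance(self, rng):
        for _ in range(20):
            n = 50
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            res = roc(scores, labels)
            assert res.auc == pytest.approx(naive_auc(scores, labels), abs=1e-12)

    def test_delong_interval_contains_auc(self, rng):
        scores = rng.normal(size=60) + np.repeat([1.0, 0.0], 30)
        labels = np.repeat([True, False], 30)
        res = roc(scores, labels)
        assert res.ci_low <= res.auc <= res.ci_high
        assert 0.0 <= res.ci_low and res.ci_high <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc([0.1, 0.2], [1, 1])


class TestSensSpec:
    def test_extreme_cutoffs(self):
        scores = [-0.8, -0.2, 0.3, 0.9]
        labels = [0, 0, 1, 1]
        assert sens_spec(scores, labels, cutoff=-1.0) == (1.0, 0.0)
        assert sens_spec(scores, labels, cutoff=1.0) == (0.0, 1.0)

    def test_counting_oracle_on_toy_scores(self):
        scores = [0.9, 0.4, 0.0, -0.1, 0.2, -0.9, 0.6, -0.4, 0.05, -0.6]
        labels = [1, 1, 1, 1, 0, 0, 0, 0, 1, 0]
        sens, spec = sens_spec(scores, labels, cutoff=0.0)
        # recurrent scores {0.9, 0.4, 0.0, -0.1, 0.05}: 3 of 5 exceed 0
        # (0.0 counts as a low call); non-recurrent {0.2,-0.9,0.6,-0.4,-0.6}: 3 of 5 <= 0
        assert sens == pytest.approx(3 / 5)
        assert spec == pytest.approx(3 / 5)


def _cohort_frames(rng, n=80, stages=("IA", "IB")):
    scores = rng.uniform(-1, 1, n)
    groups = scores > 0
    lam = 0.004 * np.where(groups, 5.0, 1.0)
    times = np.minimum(rng.exponential(1.0 / lam), 120.0)
    events = (times < 120.0).astype(int)
    score_df = pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(n)],
        "score": scores,
        "n_votes": 10,
        "call": np.where(groups, "high", "low"),
        "confidence": np.where(np.abs(scores) < 0.5, "medium_risk", "high_confidence"),
    })
    outcome_df = pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(n)],
        "class": np.where(events == 1, "recurrent", "non_recurrent"),
        "stage": rng.choice(stages, n),
        "dfs_months": times,
        "event": events,
    })
    return score_df, outcome_df


class TestEvaluateCohort:
    def test_report_has_one_block_per_stratum(self, rng):
        scores, outcomes = _cohort_frames(rng)
        report = evaluate_cohort(scores, outcomes,
                                 strata={"all": None, "IA": ("IA",), "IB": ("IB",)})
        assert set(report["strata"]) == {"all", "IA", "IB"}
        assert report["strata"]["all"]["estimable"]
        assert "classification" in report

    def test_zero_event_stratum_not_estimable(self, rng):
        scores, outcomes = _cohort_frames(rng)
        outcomes.loc[outcomes["stage"] == "IA", "event"] = 0
        report = evaluate_cohort(scores, outcomes, strata={"IA": ("IA",)})
        block = report["strata"]["IA"]
        assert block["estimable"] is False and block["reason"] == "zero events"

    def test_single_risk_group_stratum_not_estimable(self, rng):
        scores, outcomes = _cohort_frames(rng)
        scores["call"] = "high"
        report = evaluate_cohort(scores, outcomes, strata={"all": None})
        assert report["strata"]["all"]["estimable"] is False

    def test_pooling_two_identical_strata_preserves_the_hazard_ratio(self, rng):
        scores, outcomes = _cohort_frames(rng, n=60, stages=("IA",))
        dup_scores = scores.copy()
        dup_scores["sample_id"] = "D" + dup_scores["sample_id"]
        dup_out = outcomes.copy()
        dup_out["sample_id"] = "D" + dup_out["sample_id"]
        dup_out["stage"] = "IB"
        pooled = evaluate_cohort(pd.concat([scores, dup_scores]),
                                 pd.concat([outcomes, dup_out]),
                                 strata={"all": None, "IA": ("IA",)})
        single = pooled["strata"]["IA"]
        both = pooled["strata"]["all"]
        assert both["cox"]["hr"] == pytest.approx(single["cox"]["hr"], rel=1e-6)

    def test_medium_risk_samples_are_counted_but_never_excluded(self, rng):
        scores, outcomes = _cohort_frames(rng)
        report = evaluate_cohort(scores, outcomes, strata={"all": None})
        block = report["strata"]["all"]
        assert block["n_medium_risk"] > 0
        assert block["n_high"] + block["n_low"] == block["n"] == len(scores)
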