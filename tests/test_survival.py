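"""Kaplan-Meier, log-rank, Cox partial likelihood, optimal cutpoint."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as ll_logrank

from trccomics import (
    SurvivalTable,
    cox_univariate,
    km_estimate,
    logrank_test,
    optimal_cutpoint,
    simulate_survival,
)
from trccomics.survival import _breslow_loglik_grad_hess


def table(times, events, scores=None):
    df = pd.DataFrame(
        {
            "sample_id": [f"p{i}" for i in range(len(times))],
            "time": times,
            "event": events,
        }
    )
    if scores is not None:
        df["score"] = scores
    return SurvivalTable(df)


def random_table(rng, n=20):
    return table(
        rng.exponential(10, size=n).round(3) + 0.1,
        rng.integers(0, 2, size=n),
        rng.normal(size=n),
    )


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        km = km_estimate(table([1, 2, 3], [0, 0, 0]))["all"]
        assert (km["survival"] == 1.0).all()

    def test_three_events_hand_product_limit(self):
        km = km_estimate(table([1, 2, 3], [1, 1, 1]))["all"]
        s = km.set_index("time")["survival"]
        assert np.allclose([s[1.0], s[2.0], s[3.0]], [2 / 3, 1 / 3, 0.0])

    def test_censor_time_beyond_last_event_is_irrelevant(self):
        # moving a censored exit further past the last event cannot change S
        a = km_estimate(table([1, 2, 3, 5], [1, 1, 1, 0]))["all"]
        b = km_estimate(table([1, 2, 3, 500], [1, 1, 1, 0]))["all"]
        sa = a.set_index("time")["survival"]
        sb = b.set_index("time")["survival"]
        for t in (1.0, 2.0, 3.0):
            assert sa[t] == pytest.approx(sb[t])

    def test_invariant_to_record_order(self):
        times = [1.0, 2.0, 2.0, 5.0, 7.0]
        events = [1, 1, 0, 1, 0]
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(times))
        a = km_estimate(table(times, events))["all"]
        b = km_estimate(table([times[i] for i in perm], [events[i] for i in perm]))["all"]
        pd.testing.assert_frame_equal(a, b)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            table([0.0, 1.0], [1, 1])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = table([1, 2, 3, 1, 2, 3], [1, 0, 1, 1, 0, 1])
        chi2, p = logrank_test(t, list("aaabbb"))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_symmetric_in_group_labels(self):
        rng = np.random.default_rng(1)
        t = random_table(rng)
        g = rng.choice(["x", "y"], size=len(t))
        a = logrank_test(t, g)
        flipped = np.where(g == "x", "y", "x")
        b = logrank_test(t, flipped)
        assert a == pytest.approx(b)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_lifelines_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, n=int(rng.integers(8, 21)))
        g = rng.choice(["x", "y"], size=len(t))
        if t.event.sum() == 0 or len(set(g)) < 2:
            pytest.skip("degenerate draw")
        chi2, p = logrank_test(t, g)
        ref = ll_logrank(
            t.time[g == "x"], t.time[g == "y"],
            event_observed_A=t.event[g == "x"], event_observed_B=t.event[g == "y"],
        )
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_no_events_reported_missing(self):
        t = table([1, 2, 3, 4], [0, 0, 0, 0])
        chi2, p = logrank_test(t, list("aabb"))
        assert np.isnan(chi2) and np.isnan(p)


class TestCox:
    def test_matches_partial_likelihood_grid_search(self):
        rng = np.random.default_rng(2)
        t = random_table(rng, n=15)
        fit = cox_univariate(t, "score")
        x = t.table["score"].to_numpy()
        xs = (x - x.mean()) / x.std()
        grid = np.arange(-3, 3, 1e-3)
        lls = [
            _breslow_loglik_grad_hess(b, t.time, t.event, xs)[0] for b in grid
        ]
        beta_grid = grid[int(np.argmax(lls))] / x.std()
        assert fit.beta == pytest.approx(beta_grid, abs=2e-3 / x.std())

    def test_matches_lifelines_breslow(self):
        rng = np.random.default_rng(3)
        t = random_table(rng, n=40)
        fit = cox_univariate(t, "score")
        cph = CoxPHFitter()
        cph.fit(
            t.table[["time", "event", "score"]],
            duration_col="time",
            event_col="event",
        )
        # few ties in continuous times: Efron and Breslow agree closely
        assert fit.beta == pytest.approx(cph.params_["score"], abs=1e-3)
        assert fit.se == pytest.approx(cph.standard_errors_["score"], rel=1e-2)

    def test_recovers_planted_beta(self):
        rng = np.random.default_rng(4)
        scores = pd.Series(rng.normal(size=300), index=[f"p{i}" for i in range(300)])
        surv = simulate_survival(scores, beta=1.0, censor_rate=0.2, seed=5)
        fit = cox_univariate(surv.join_scores(scores, "score"), "score")
        assert abs(fit.beta - 1.0) < 0.2
        assert fit.converged

    def test_hazard_ratio_of_binary_covariate_matches_group_hazards(self):
        rng = np.random.default_rng(6)
        group = pd.Series(
            np.repeat([0.0, 1.0], 1000), index=[f"p{i}" for i in range(2000)]
        )
        surv = simulate_survival(group, beta=np.log(3.0), censor_rate=0.0, seed=7)
        fit = cox_univariate(surv.join_scores(group, "grp"), "grp")
        assert fit.hazard_ratio == pytest.approx(3.0, rel=0.10)

    def test_separation_flagged_and_capped(self):
        # all events in one group before any in the other -> monotone likelihood
        t = table([1, 2, 3, 10, 11, 12], [1, 1, 1, 1, 1, 1], [1, 1, 1, 0, 0, 0])
        fit = cox_univariate(t, "score")
        assert fit.separation
        assert np.isfinite(fit.beta)

    def test_validation_errors(self):
        t = table([1, 2], [0, 0], [0.5, 1.5])
        with pytest.raises(ValueError, match="events"):
            cox_univariate(t, "score")
        t2 = table([1, 2], [1, 1], [1.0, 1.0])
        with pytest.raises(ValueError, match="constant"):
            cox_univariate(t2, "score")


class TestOptimalCutpoint:
    def test_indicator_score_threshold_separates_planted_groups(self):
        rng = np.random.default_rng(8)
        indicator = pd.Series(
            np.repeat([0.0, 1.0], 25), index=[f"p{i}" for i in range(50)]
        )
        surv = simulate_survival(indicator, beta=2.0, censor_rate=0.1, seed=9)
        cut = optimal_cutpoint(surv.join_scores(indicator, "grp"), "grp", minprop=0.1)
        assert 0.0 < cut.threshold < 1.0
        assert (cut.groups == "high").sum() == 25

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(12, 31))
        t = random_table(rng, n=n)
        if t.event.sum() < 2:
            pytest.skip("too few events")
        minprop = 0.15
        cut = optimal_cutpoint(t, "score", minprop=minprop, fit_cox=False)
        x = t.table["score"].to_numpy()
        best = (-np.inf, None)
        for thr in (np.unique(x)[:-1] + np.unique(x)[1:]) / 2:
            high = x > thr
            if min(high.sum(), n - high.sum()) < minprop * n:
                continue
            chi2, _ = logrank_test(t, np.where(high, "h", "l"))
            z = np.sqrt(chi2)
            if z > best[0] + 1e-12:
                best = (z, thr)
        assert cut.threshold == pytest.approx(best[1])
        assert cut.statistic == pytest.approx(best[0], rel=1e-9)

    def test_minprop_constrains_admissible_splits(self):
        t = table(np.arange(1, 11, dtype=float), [1] * 10, np.arange(10, dtype=float))
        cut = optimal_cutpoint(t, "score", minprop=0.4, fit_cox=False)
        n_high = (cut.groups == "high").sum()
        assert 4 <= n_high <= 6

    def test_statistic_bounds_any_admissible_threshold(self):
        rng = np.random.default_rng(10)
        t = random_table(rng, n=25)
        cut = optimal_cutpoint(t, "score", minprop=0.1, fit_cox=False)
        x = t.table["score"].to_numpy()
        for thr in np.quantile(x, [0.2, 0.4, 0.6, 0.8]):
            high = x > thr
            if min(high.sum(), len(x) - high.sum()) < 0.1 * len(x):
                continue
            chi2, _ = logrank_test(t, np.where(high, "h", "l"))
            assert cut.statistic >= np.sqrt(chi2) - 1e-9

    def test_result_flags_optimistic_p_and_reports_cox(self):
        rng = np.random.default_rng(11)
        scores = pd.Series(rng.normal(size=60), index=[f"p{i}" for i in range(60)])
        surv = simulate_survival(scores, beta=1.5, censor_rate=0.2, seed=12)
        cut = optimal_cutpoint(surv.join_scores(scores, "s"), "s")
        assert cut.p_is_optimistic
        assert cut.cox is not None and cut.cox.hazard_ratio > 1.0
        assert "optimistic" in cut.summary()

    def test_constant_score_rejected(self):
        t = table([1, 2, 3, 4], [1, 1, 0, 1], [2.0, 2.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            optimal_cutpoint(t, "score")
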