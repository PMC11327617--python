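"""From-scratch survival statistics against brute-force and library oracles.

lifelines serves purely as an independent reference implementation here; the
package's own estimators never call it.
"""

import numpy as np
import pandas as pd
import pytest

from gliosurv import metrics as M


def brute_force_ctd(cif_matrix, times, events):
    n = len(times)
    num, den = 0.0, 0
    for i in range(n):
        for j in range(n):
            if i != j and times[i] < times[j] and events[i] == 1:
                den += 1
                if cif_matrix[i, i] > cif_matrix[i, j]:
                    num += 1.0
                elif np.isclose(cif_matrix[i, i], cif_matrix[i, j]):
                    num += 0.5
    return num / den


class TestCtd:
    def test_perfect_ordering_gives_one(self):
        n = 10
        times = np.arange(1.0, n + 1)
        events = np.ones(n, dtype=int)
        risk = n - np.arange(n, dtype=float)  # earlier subjects riskier
        cif_matrix = np.tile(risk / n, (n, 1))
        assert M.ctd(cif_matrix, times, events) == 1.0

    def test_identical_predictions_give_half(self):
        times = np.arange(1.0, 9.0)
        events = np.ones(8, dtype=int)
        assert M.ctd(np.full((8, 8), 0.3), times, events) == 0.5

    def test_matches_brute_force_on_random_instance(self, rng):
        n = 20
        times = rng.exponential(300, size=n)
        events = rng.integers(0, 2, size=n)
        events[0] = 1
        cm = rng.uniform(size=(n, n))
        assert M.ctd(cm, times, events) == brute_force_ctd(cm, times, events)

    def test_no_comparable_pairs_raises(self):
        with pytest.raises(ValueError, match="comparable"):
            M.ctd(np.zeros((2, 2)), [1.0, 2.0], [0, 0])


class TestKaplanMeier:
    def test_two_subject_closed_form(self):
        km = M.km_estimator([1.0, 2.0], [1, 1])
        assert km(1.0) == 0.5
        assert km(2.0) == 0.0

    def test_all_censored_is_flat_one(self):
        km = M.km_estimator([5.0, 8.0, 2.0], [0, 0, 0])
        assert km(10.0) == 1.0

    def test_hand_product_limit_with_censoring(self):
        km = M.km_estimator([1.0, 1.5, 2.0, 3.0], [1, 0, 1, 0])
        assert km(1.0) == pytest.approx(0.75)
        assert km(2.0) == pytest.approx(0.375)

    def test_no_censoring_equals_empirical_tail(self, rng):
        t = rng.exponential(1.0, size=40)
        km = M.km_estimator(t, np.ones(40, dtype=int))
        for q in np.quantile(t, [0.2, 0.5, 0.8]):
            assert km(q) == pytest.approx((t > q).mean(), abs=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(1.0, size=80)
        e = rng.integers(0, 2, size=80)
        km = M.km_estimator(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        qs = np.quantile(t, [0.1, 0.4, 0.7, 0.95])
        np.testing.assert_allclose(
            km(qs), kmf.survival_function_at_times(qs).values, atol=1e-12
        )


class TestBrierScore:
    def test_oracle_predictions_score_zero(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.ones(4, dtype=int)
        G = M.censoring_km(times, events)
        for t in (0.5, 1.5, 2.5, 3.5):
            surv = (times > t).astype(float)  # S(t)=1 before event, 0 after
            assert M.brier_score(surv, times, events, t, G) == pytest.approx(0.0)

    def test_constant_half_scores_quarter(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.ones(4, dtype=int)
        G = M.censoring_km(times, events)
        assert M.brier_score(np.full(4, 0.5), times, events, 2.5, G) == pytest.approx(0.25)

    def test_five_subject_censored_hand_computation(self):
        """Term-by-term evaluation with KM censoring weights."""
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        events = np.array([1, 0, 1, 0, 1])
        S = np.array([0.9, 0.8, 0.4, 0.6, 0.7])
        t = 3.5
        G = M.censoring_km(times, events)
        # G jumps at censoring times 2 and 4: G(2)=0.75, G(4)=0.375
        terms = [
            S[0] ** 2 / G.left_limit(1.0),  # died before t, weight 1/G(1-)=1
            0.0,  # censored at 2 < t
            S[2] ** 2 / G.left_limit(3.0),  # died at 3, G(3-)=0.75
            (1 - S[3]) ** 2 / G(t),  # still at risk at 3.5, G(3.5)=0.75
            (1 - S[4]) ** 2 / G(t),
        ]
        expected = np.mean(terms)
        assert M.brier_score(S, times, events, t, G) == pytest.approx(expected, abs=1e-12)

    def test_zero_censoring_weight_raises(self):
        times = np.array([1.0, 2.0])
        events = np.array([1, 1])
        G_zero = M.StepFunction(jump_times=np.array([0.5]), values=np.array([0.0]))
        with pytest.raises(ZeroDivisionError):
            M.brier_score(np.array([0.5, 0.5]), times, events, 1.5, G_zero)


class TestIntegratedBrier:
    def test_constant_integrand(self):
        assert M.integrated_brier([0.1] * 5, [1, 2, 3, 4, 5]) == pytest.approx(0.1)

    def test_linear_integrand(self):
        assert M.integrated_brier([0.0, 0.2], [0.0, 10.0]) == pytest.approx(0.1)

    def test_matches_fine_grid_refinement(self, rng):
        ts = np.linspace(1, 24, 24)
        bs = rng.uniform(0, 0.3, size=24)
        coarse = M.integrated_brier(bs, ts)
        fine_t = np.linspace(1, 24, 2301)
        fine_b = np.interp(fine_t, ts, bs)
        fine = np.trapezoid(fine_b, fine_t) / (fine_t[-1] - fine_t[0])
        assert coarse == pytest.approx(fine, abs=1e-9)

    def test_degenerate_range_raises(self):
        with pytest.raises(ValueError):
            M.integrated_brier([0.1], [1.0])


class TestLogrank:
    def test_identical_groups_give_zero(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        e = np.array([1, 1, 0, 1, 1, 0])
        g = np.array([0, 0, 0, 1, 1, 1])
        chi2, p = M.logrank_test(g, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_worked_six_subject_example(self):
        """O/E/V tabulation by hand for times (1,2,3) in group 1 (all events)
        vs (4,5,6) in group 0 (all events)."""
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.ones(6, dtype=int)
        g = np.array([1, 1, 1, 0, 0, 0])
        # event at 1: n=6, n1=3, E=0.5, V=0.25*... hand-accumulated:
        o_minus_e = (1 - 3 / 6) + (1 - 2 / 5) + (1 - 1 / 4)
        var = (3 / 6) * (1 - 3 / 6) + (2 / 5) * (1 - 2 / 5) + (1 / 4) * (1 - 1 / 4)
        chi2_hand = o_minus_e**2 / var
        chi2, _ = M.logrank_test(g, t, e)
        assert chi2 == pytest.approx(chi2_hand, abs=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll

        t = rng.exponential(1.0, size=60)
        e = rng.integers(0, 2, size=60)
        g = rng.integers(0, 2, size=60)
        chi2, p = M.logrank_test(g, t, e)
        ref = ll(t[g == 1], t[g == 0], e[g == 1], e[g == 0])
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-9)
        assert p == pytest.approx(ref.p_value, abs=1e-12)


class TestCox:
    def test_four_subject_grid_search_oracle(self):
        """All-event, binary-covariate instance: the Newton fit equals the
        maximizer found by dense grid search over β."""
        x = np.array([1.0, 0.0, 1.0, 0.0])
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, dtype=int)
        fit = M.fit_cox(x, t, e)

        def pll(beta):
            ll, _, _ = M._cox_derivatives(np.array([beta]), x[:, None], t, e)
            return ll

        grid = np.linspace(-5, 5, 20001)
        best = grid[np.argmax([pll(b) for b in grid])]
        assert fit.coef[0] == pytest.approx(best, abs=1e-3)

    def test_duplicating_subjects_leaves_estimate_unchanged(self, rng):
        x = rng.normal(size=(30, 2))
        t = rng.exponential(1 / np.exp(x @ [0.8, -0.4]))
        e = np.ones(30, dtype=int)
        f1 = M.fit_cox(x, t, e)
        f2 = M.fit_cox(np.vstack([x, x]), np.concatenate([t, t]), np.concatenate([e, e]))
        np.testing.assert_allclose(f1.coef, f2.coef, atol=1e-6)

    def test_matches_lifelines_coefficients_and_se(self, rng):
        from lifelines import CoxPHFitter

        n = 150
        x = rng.normal(size=(n, 2))
        t = rng.exponential(1 / np.exp(x @ [1.0, -0.5]))
        c = rng.exponential(2.0, size=n)
        times, events = np.minimum(t, c), (t <= c).astype(int)
        fit = M.fit_cox(x, times, events)
        df = pd.DataFrame({"x0": x[:, 0], "x1": x[:, 1], "T": times, "E": events})
        ref = CoxPHFitter().fit(df, "T", "E")
        # lifelines converges under its own (looser) criterion; both sit at
        # the same optimum
        np.testing.assert_allclose(fit.coef, ref.params_.values, atol=1e-4)
        np.testing.assert_allclose(fit.se, ref.standard_errors_.values, atol=1e-4)

    def test_constant_covariate_raises(self):
        with pytest.raises(ValueError, match="constant"):
            M.fit_cox(np.ones(10), np.arange(1.0, 11.0), np.ones(10, dtype=int))

    def test_null_covariate_stays_near_zero(self, rng):
        """Permuted (outcome-independent) covariate: |β̂| < 0.2 in at least
        95% of replicates at n = 500."""
        hits = 0
        reps = 40
        for _ in range(reps):
            x = rng.normal(size=500)
            t = rng.exponential(1.0, size=500)
            fit = M.fit_cox(x, t, np.ones(500, dtype=int))
            hits += abs(fit.coef[0]) < 0.2
        assert hits / reps >= 0.95


class TestSchoenfeld:
    def _sim(self, rng, n=200):
        x = rng.normal(size=(n, 2))
        t = rng.exponential(1 / np.exp(x @ [1.0, -0.5]))
        c = rng.exponential(2.0, size=n)
        return x, np.minimum(t, c), (t <= c).astype(int)

    def test_residuals_sum_to_zero_at_mle(self, rng):
        x, times, events = self._sim(rng)
        fit = M.fit_cox(x, times, events)
        resid, _, _ = M.schoenfeld_residuals(fit, x, times, events)
        np.testing.assert_allclose(resid.sum(axis=0), 0.0, atol=1e-6)

    def test_matches_lifelines_km_transform(self, rng):
        from lifelines import CoxPHFitter
        from lifelines.statistics import proportional_hazard_test

        x, times, events = self._sim(rng)
        fit = M.fit_cox(x, times, events)
        p = M.schoenfeld_ph_test(fit, x, times, events)
        df = pd.DataFrame({"x0": x[:, 0], "x1": x[:, 1], "T": times, "E": events})
        cph = CoxPHFitter().fit(df, "T", "E")
        ref = proportional_hazard_test(cph, df, time_transform="km")
        np.testing.assert_allclose(
            [p[0], p[1]], ref.summary["p"].values, atol=1e-6
        )

    def test_too_few_events_raise(self):
        fit = M.CoxFit(coef=np.zeros(1), cov=np.eye(1), n_iter=1, loglik=0.0)
        with pytest.raises(ValueError, match="events"):
            M.schoenfeld_ph_test(fit, np.arange(5.0), np.arange(1.0, 6.0), [1, 0, 0, 0, 1])


class TestDichotomize:
    def test_never_crossing_half_is_favorable(self):
        S = np.full((1, 24), 0.8)
        assert M.dichotomize(S, 12.0)[0] == 1

    def test_early_drop_is_unfavorable(self):
        S = np.linspace(1.0, 0.0, 24)[None, :]  # falls below 0.5 around month 12
        S = np.where(np.arange(1, 25) >= 6, 0.4, 0.9)[None, :]
        assert M.dichotomize(S, 12.0)[0] == 0

    def test_crossing_exactly_at_threshold_is_unfavorable(self):
        S = np.ones((1, 24))
        S[0, 11:] = 0.4  # first month below 0.5 is month 12
        med = M.predicted_median_months(S)
        assert med[0] == 12
        assert M.dichotomize(S, 12.0)[0] == 0
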