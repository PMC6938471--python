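"""Cox regression, screening, Farrar-Glauber and Kaplan-Meier."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adcsurv.survival import (
    ConvergenceError, CoxResult, cox_fit, cox_loglik, cox_univariate,
    farrar_glauber, kaplan_meier, km_frame, screen_covariates,
)


def brute_force_cox(beta, X, time, event):
    """Risk-set product enumeration for small untied samples.

    Log partial likelihood and score computed naively, one event at a
    time, with explicit risk-set sums.
    """
    X = np.atleast_2d(X)
    if X.shape[0] != len(time):
        X = X.T
    beta = np.atleast_1d(beta)
    ll = 0.0
    score = np.zeros(X.shape[1])
    for i in range(len(time)):
        if not event[i]:
            continue
        risk = [j for j in range(len(time)) if time[j] >= time[i]]
        denom = sum(math.exp(float(X[j] @ beta)) for j in risk)
        num = sum(math.exp(float(X[j] @ beta)) * X[j] for j in risk)
        ll += float(X[i] @ beta) - math.log(denom)
        score += X[i] - num / denom
    return ll, score


class TestCoxPartialLikelihood:
    def _small(self, rng, n=8, p=2):
        X = rng.normal(0, 1, (n, p))
        time = rng.uniform(1, 100, n)  # continuous: no ties
        event = rng.random(n) < 0.8
        event[0] = True
        return X, time, event

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(20):
            X, time, event = self._small(rng)
            beta = rng.normal(0, 0.5, 2)
            ll, grad, _ = cox_loglik(beta, X, time, event)
            want_ll, want_score = brute_force_cox(beta, X, time, event)
            assert ll == pytest.approx(want_ll, abs=1e-10)
            assert grad == pytest.approx(want_score, abs=1e-10)

    def test_six_subject_worked_instance(self):
        time = np.array([3.0, 5.0, 7.0, 11.0, 13.0, 17.0])
        event = np.array([True, True, False, True, True, True])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        beta = np.array([0.7])
        ll, grad, _ = cox_loglik(beta, x[:, None], time, event)
        want_ll, want_score = brute_force_cox(beta, x[:, None], time, event)
        assert ll == pytest.approx(want_ll, abs=1e-10)
        assert grad[0] == pytest.approx(want_score[0], abs=1e-10)

    def test_wald_statistics_against_lifelines(self, rng):
        from lifelines import CoxPHFitter
        n = 80
        x = rng.integers(0, 2, n).astype(float)
        time = rng.exponential(1.0 / (0.01 * np.exp(0.7 * x)))
        event = rng.random(n) < 0.85
        event[:2] = True
        res = cox_univariate(x, time, event, name="x")
        df = pd.DataFrame({"t": time, "e": event.astype(int), "x": x})
        cph = CoxPHFitter().fit(df, "t", "e")
        assert res.coef == pytest.approx(cph.params_["x"], abs=1e-5)
        assert res.p_value == pytest.approx(cph.summary["p"]["x"], abs=1e-5)

    def test_efron_tie_handling_against_lifelines(self, rng):
        from lifelines import CoxPHFitter
        n = 60
        x = rng.integers(0, 2, n).astype(float)
        time = np.ceil(rng.exponential(20 / np.exp(0.5 * x)))  # heavy ties
        event = rng.random(n) < 0.9
        event[:2] = True
        res = cox_univariate(x, time, event, name="x")
        df = pd.DataFrame({"t": time, "e": event.astype(int), "x": x})
        cph = CoxPHFitter().fit(df, "t", "e")  # lifelines uses Efron
        assert res.coef == pytest.approx(cph.params_["x"], abs=1e-4)

    def test_label_swap_inverts_hazard_ratio(self, rng):
        n = 50
        x = rng.integers(0, 2, n).astype(float)
        time = rng.exponential(1.0 / (0.02 * np.exp(0.9 * x)))
        event = np.ones(n, bool)
        a = cox_univariate(x, time, event, name="x")
        b = cox_univariate(1.0 - x, time, event, name="x_swapped")
        assert b.coef == pytest.approx(-a.coef, abs=1e-8)
        assert b.hr == pytest.approx(1.0 / a.hr, rel=1e-8)
        assert b.p_value == pytest.approx(a.p_value, abs=1e-10)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            cox_univariate([0, 1, 0, 1], [1, 2, 3, 4],
                           [False] * 4, name="x")

    def test_complete_separation_detected(self):
        # all events in one group, occurring strictly before the other group
        x = np.array([1.0] * 5 + [0.0] * 5)
        time = np.concatenate([np.arange(1, 6), np.arange(10, 15)])
        event = np.array([True] * 5 + [False] * 5)
        with pytest.raises(ConvergenceError, match="x"):
            cox_univariate(x, time, event, name="x")


class TestScreening:
    def _results(self, ps):
        return [CoxResult(name=f"m{i}", coef=0.0, hr=1.0, ci_lower=0.5,
                          ci_upper=2.0, p_value=p, n=43, n_events=40)
                for i, p in enumerate(ps)]

    def test_threshold_keeps_table_marked_covariates(self):
        # the screening pattern of the headline univariate results:
        # 0.044 and 0.073 pass at p < 0.1, 0.39 does not
        selected = screen_covariates(self._results([0.044, 0.073, 0.39]), 0.1)
        assert selected == ["m0", "m1"]

    def test_exactly_at_threshold_not_selected(self):
        assert screen_covariates(self._results([0.1]), 0.1) == []

    def test_empty_results_give_empty_selection(self):
        assert screen_covariates([], 0.1) == []


class TestFarrarGlauber:
    def _sample_with_corr(self, rng, R, n=200):
        p = R.shape[0]
        L = np.linalg.cholesky(R)
        return rng.normal(0, 1, (n, p)) @ L.T

    def test_orthogonal_covariates_give_zero(self):
        # 2^3 factorial design: pairwise correlations exactly zero
        import itertools
        X = np.array(list(itertools.product([-1.0, 1.0], repeat=3)))
        res = farrar_glauber(X)
        assert res.chi_square == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(res.f_statistics, 0.0, atol=1e-10)
        off = res.partial_corr[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.0, atol=1e-10)

    def test_p2_closed_form(self, rng):
        # chi-square = -(n - 1 - 9/6) * ln(1 - r^2) for two covariates
        n = 43
        z = rng.normal(0, 1, n)
        x2 = 0.9 * z + math.sqrt(1 - 0.81) * rng.normal(0, 1, n)
        X = np.column_stack([z, x2])
        r = np.corrcoef(X, rowvar=False)[0, 1]
        res = farrar_glauber(X)
        want = -(n - 1 - 9 / 6.0) * math.log(1 - r ** 2)
        assert res.chi_square == pytest.approx(want, abs=1e-10)
        assert res.chi_square_df == 1

    @pytest.mark.parametrize("p", [2, 3, 4, 5])
    def test_formulas_match_direct_evaluation(self, rng, p):
        R = np.full((p, p), 0.5) + 0.5 * np.eye(p)
        X = self._sample_with_corr(rng, R, n=100)
        n = X.shape[0]
        res = farrar_glauber(X)
        Rhat = np.corrcoef(X, rowvar=False)
        want_chi2 = -(n - 1 - (2 * p + 5) / 6.0) * math.log(np.linalg.det(Rhat))
        assert res.chi_square == pytest.approx(want_chi2, abs=1e-10)
        Rinv = np.linalg.inv(Rhat)
        for i in range(p):
            want_f = (Rinv[i, i] - 1) * (n - p) / (p - 1)
            assert res.f_statistics[i] == pytest.approx(want_f, abs=1e-10)
            for j in range(p):
                if i == j:
                    continue
                want_r = -Rinv[i, j] / math.sqrt(Rinv[i, i] * Rinv[j, j])
                assert res.partial_corr[i, j] == pytest.approx(want_r, abs=1e-10)

    def test_partial_corr_symmetric_unit_diagonal(self, rng):
        X = rng.normal(0, 1, (60, 4))
        res = farrar_glauber(X)
        assert np.allclose(res.partial_corr, res.partial_corr.T)
        assert np.allclose(np.diag(res.partial_corr), 1.0)
        assert np.all(np.abs(res.partial_corr) <= 1.0)

    def test_monotone_in_pairwise_correlation(self, rng):
        chis = []
        for r in (0.2, 0.5, 0.8):
            z = rng.normal(0, 1, 500)
            x2 = r * z + math.sqrt(1 - r * r) * rng.normal(0, 1, 500)
            chis.append(farrar_glauber(np.column_stack([z, x2])).chi_square)
        assert chis[0] < chis[1] < chis[2]

    def test_singular_design_reports_collinear_columns(self, rng):
        z = rng.normal(0, 1, 30)
        X = np.column_stack([z, 2 * z, rng.normal(0, 1, 30)])
        with pytest.raises(np.linalg.LinAlgError):
            farrar_glauber(X, names=["a", "a_copy", "b"])


class TestKaplanMeier:
    def test_four_subject_hand_calculation(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0])
        event = np.ones(8, bool)
        group = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        curve = kaplan_meier(time, event, group)
        for g in curve.groups.values():
            assert np.allclose(g.survival, [0.75, 0.50, 0.25, 0.0])
            assert g.median == 2.0

    def test_all_censored_curve_stays_at_one(self):
        time = np.array([5.0, 6.0, 7.0, 8.0])
        event = np.zeros(4, bool)
        group = np.array([0, 0, 1, 1])
        curve = kaplan_meier(time, event, group)
        for g in curve.groups.values():
            assert g.times.size == 0
            assert math.isnan(g.median)

    def test_record_duplication_leaves_curve_unchanged(self, rng):
        n = 20
        time = rng.uniform(1, 50, n)
        event = rng.random(n) < 0.7
        group = rng.integers(0, 2, n)
        group[:2] = [0, 1]
        a = kaplan_meier(time, event, group)
        b = kaplan_meier(np.tile(time, 2), np.tile(event, 2), np.tile(group, 2))
        for label in a.groups:
            assert np.allclose(a.groups[label].survival, b.groups[label].survival)
            assert np.allclose(a.groups[label].times, b.groups[label].times)

    def test_no_censoring_equals_empirical_survival(self, rng):
        time = rng.uniform(1, 100, 30)
        event = np.ones(30, bool)
        group = np.concatenate([np.zeros(15, int), np.ones(15, int)])
        curve = kaplan_meier(time, event, group)
        for level, label in ((0, "negative"), (1, "positive")):
            t_g = np.sort(time[group == level])
            g = curve.groups[label]
            empirical = [(t_g > t).mean() for t in g.times]
            assert np.allclose(g.survival, empirical, atol=1e-12)

    def test_survival_non_increasing_and_ci_brackets(self, rng):
        time = rng.exponential(30, 40)
        event = rng.random(40) < 0.7
        event[:2] = True
        group = rng.integers(0, 2, 40)
        group[:2] = [0, 1]
        curve = kaplan_meier(time, event, group)
        for g in curve.groups.values():
            assert np.all(np.diff(g.survival) <= 1e-15)
            assert np.all(g.ci_lower <= g.survival + 1e-12)
            assert np.all(g.ci_upper >= g.survival - 1e-12)

    def test_matches_lifelines_estimates(self, rng):
        from lifelines import KaplanMeierFitter
        time = rng.exponential(30, 50)
        event = rng.random(50) < 0.6
        event[:2] = True
        group = np.zeros(50, int)
        group[25:] = 1
        curve = kaplan_meier(time, event, group)
        for level, label in ((0, "negative"), (1, "positive")):
            kmf = KaplanMeierFitter().fit(time[group == level],
                                          event[group == level])
            g = curve.groups[label]
            got = g.survival
            want = kmf.survival_function_at_times(g.times).to_numpy()
            assert np.allclose(got, want, atol=1e-10)

    def test_frame_is_tidy(self, rng):
        time = rng.uniform(1, 30, 12)
        event = np.ones(12, bool)
        group = np.tile([0, 1], 6)
        df = km_frame(kaplan_meier(time, event, group))
        assert set(df["group"]) == {"negative", "positive"}
        assert list(df.columns) == ["group", "time", "survival",
                                    "ci_lower", "ci_upper"]
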