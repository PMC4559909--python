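import numpy as np
import pytest

from vegfsema import survival
from vegfsema.survival import (
    compare_survival_by_class, cox_fit, cox_score_test, kaplan_meier, log_rank,
)


class TestKaplanMeier:
    def test_hand_worked_product_limit(self):
        # events at 1 and 2, censoring at 3, event at 4
        km = kaplan_meier([1, 2, 3, 4], [True, True, False, True])
        assert np.allclose(km.survival, [0.75, 0.50, 0.0])
        assert km.survival_at(3.5) == pytest.approx(0.50)

    def test_no_events_flat_at_one(self):
        km = kaplan_meier([1, 2, 3], [False, False, False])
        assert km.survival_at(100.0) == 1.0

    def test_all_events_at_once_drops_to_zero(self):
        km = kaplan_meier([1, 1, 1], [True, True, True])
        assert km.survival_at(1.0) == 0.0

    def test_invariants_on_random_data(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(2, size=50)
        e = rng.uniform(size=50) > 0.4
        km = kaplan_meier(t, e)
        assert km.survival_at(0.0) <= 1.0
        assert (np.diff(km.survival) <= 1e-15).all()
        assert ((km.survival >= 0) & (km.survival <= 1)).all()

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            kaplan_meier([], [])

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(1)
        t = rng.exponential(3, size=40)
        e = rng.uniform(size=40) > 0.3
        km = kaplan_meier(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for u, s in zip(km.event_times, km.survival):
            assert kmf.predict(u) == pytest.approx(s, abs=1e-10)


class TestLogRank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0]
        e = [True, True, False]
        res = log_rank(t, e, t, e)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_worked_risk_set_enumeration(self):
        # A events at {1, 2}; B events at {3, 4}: O_A=2, E_A=5/6, Var=17/36
        res = log_rank([1, 2], [True, True], [3, 4], [True, True])
        assert res.observed[0] == pytest.approx(2.0)
        assert res.expected[0] == pytest.approx(5 / 6, abs=1e-12)
        assert res.chi2 == pytest.approx((2 - 5 / 6) ** 2 / (17 / 36), abs=1e-12)
        assert res.chi2 == pytest.approx(2.88, abs=0.01)

    def test_group_swap_invariance(self):
        rng = np.random.default_rng(2)
        ta, tb = rng.exponential(2, 20), rng.exponential(3, 25)
        ea, eb = rng.uniform(size=20) > 0.3, rng.uniform(size=25) > 0.3
        r1 = log_rank(ta, ea, tb, eb)
        r2 = log_rank(tb, eb, ta, ea)
        assert r1.chi2 == pytest.approx(r2.chi2, abs=1e-10)

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            log_rank([], [], [1.0], [True])

    def test_type_one_error_near_nominal(self):
        """Null rejection rate at alpha=0.05 stays at or below ~0.06."""
        rng = np.random.default_rng(3)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            t = rng.exponential(1, size=40)
            e = rng.uniform(size=40) > 0.25
            res = log_rank(t[:20], e[:20], t[20:], e[20:])
            rejections += res.p < 0.05
        assert rejections / n_sim <= 0.06

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test
        rng = np.random.default_rng(4)
        ta, tb = rng.exponential(2, 30), rng.exponential(1, 30)
        ea = np.ones(30, bool)
        res = log_rank(ta, ea, tb, ea)
        ref = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=ea)
        assert res.chi2 == pytest.approx(ref.test_statistic, rel=1e-8)


class TestCox:
    @staticmethod
    def _simulate(beta, n, seed, binary=False):
        rng = np.random.default_rng(seed)
        x = (rng.integers(0, 2, n).astype(float) if binary
             else rng.normal(size=n))
        t = rng.exponential(1.0, n) / np.exp(beta * x)
        c = rng.uniform(0, 3, n)
        e = t <= c
        return np.minimum(t, c), e, x

    def test_loglik_trace_nondecreasing(self):
        t, e, x = self._simulate(1.0, 100, 0)
        fit = cox_fit(t, e, x)
        assert fit.converged
        assert (np.diff(fit.loglik_trace) >= -1e-10).all()

    def test_parameter_recovery(self):
        t, e, x = self._simulate(1.0, 500, 1)
        fit = cox_fit(t, e, x)
        assert 0.8 <= fit.coef[0] <= 1.2

    def test_null_coverage_two_se(self):
        """Covariate independent of hazard: |beta| < 2 SE in >=95% of sims."""
        covered = 0
        n_sim = 300
        for seed in range(n_sim):
            t, e, x = self._simulate(0.0, 60, seed + 10)
            fit = cox_fit(t, e, x)
            covered += abs(fit.coef[0]) < 2 * fit.se[0]
        assert covered / n_sim >= 0.93

    def test_score_test_equals_log_rank_binary_no_ties(self):
        for seed in range(5):
            t, e, x = self._simulate(0.5, 60, seed, binary=True)
            assert len(np.unique(t)) == len(t)
            chi2, _ = cox_score_test(t, e, x)
            g1 = x > 0.5
            lr = log_rank(t[g1], e[g1], t[~g1], e[~g1])
            assert chi2 == pytest.approx(lr.chi2, abs=1e-6)

    def test_matches_lifelines_coefficient(self):
        import pandas as pd
        from lifelines import CoxPHFitter
        t, e, x = self._simulate(0.7, 200, 5)
        fit = cox_fit(t, e, x)
        df = pd.DataFrame({"t": t, "e": e.astype(int), "x": x})
        ref = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert fit.coef[0] == pytest.approx(ref.params_["x"], abs=1e-4)
        assert fit.se[0] == pytest.approx(ref.standard_errors_["x"], abs=1e-4)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit([1, 2, 3, 4], [True, True, False, True], np.ones(4))


class TestSurvivalByClass:
    def test_aggressive_class_has_worse_survival(self, bcr_cohort):
        from vegfsema.plsda import fit_plsda, outcome_design, select_outcome_cohort
        m, _ = bcr_cohort
        sel = select_outcome_cohort(m)
        X, y, genes = outcome_design(sel)
        model = fit_plsda(X, y, feature_names=genes)
        annotated = m.select_samples(
            list(m.metadata.index[m.metadata["bcr_event"].notna()]))
        curves, lr = compare_survival_by_class(annotated, model)
        horizon = 8.0
        assert (curves["aggressive"].survival_at(horizon)
                < curves["indolent"].survival_at(horizon))
        assert lr.p < 0.01

    def test_gleason_adjusted_cox_still_prognostic(self, bcr_cohort):
        """PLS score keeps an independent effect next to a correlated grade."""
        from vegfsema.plsda import fit_plsda, outcome_design, select_outcome_cohort
        m, truth = bcr_cohort
        sel = select_outcome_cohort(m)
        X, y, genes = outcome_design(sel)
        model = fit_plsda(X, y, feature_names=genes)
        annotated = m.select_samples(
            list(m.metadata.index[m.metadata["bcr_event"].notna()]))
        score = model.decision_function(annotated.values.to_numpy())
        rng = np.random.default_rng(0)
        pseudo_gleason = 7 + (truth.risk_scores.loc[annotated.sample_ids] > 0
                              ).astype(float) + rng.integers(-1, 2, len(score))
        t = annotated.metadata["bcr_time_years"].astype(float).to_numpy()
        e = annotated.metadata["bcr_event"].astype(bool).to_numpy()
        fit = cox_fit(t, e, np.column_stack([score, pseudo_gleason]))
        assert fit.coef[0] > 0
        assert fit.p[0] < 0.05
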