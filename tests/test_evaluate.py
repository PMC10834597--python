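"""Recommendation-effect metrics: consistency, IPTW, KM, log-rank, Cox HR,
RMST/RD, IPCW Brier, comparators and the assembled report."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank

import snbsurv as sb
from snbsurv.cox import cox_partial_loglik
from snbsurv.curves import SurvivalCurve
from snbsurv.evaluate import (brier_scores, cox_hr, evaluate, iptw_weights,
                              kaplan_meier, label_consistency, logrank_test,
                              rule_recommender, standardized_mean_differences,
                              tlearner_cph, _full_rank_columns)


class TestLabelConsistency:
    def test_elementwise_cases(self):
        assert label_consistency([1, 1], [1, 1]).all()
        assert not label_consistency([1, 0], [0, 1]).any()
        out = label_consistency([1, 0, 1], [1, 1, 1])
        assert out.tolist() == [True, False, True]

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            label_consistency([1, 0], [1])


class TestIptwWeights:
    def test_null_confounding_gives_unit_stabilized_weights(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4000, 3))
        g = rng.integers(0, 2, size=4000)
        w = iptw_weights(X, g).weights
        assert np.abs(w - 1.0).max() < 0.1

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([rng.normal(size=500), np.full(500, 3.0)])
        g = (rng.random(500) < 1 / (1 + np.exp(-X[:, 0]))).astype(int)
        with pytest.warns(UserWarning, match="constant"):
            w = iptw_weights(X, g)
        assert 1 in w.dropped_columns

    def test_balance_restored_on_confounded_cohort(self):
        data, _ = sb.generate_cohort(sb.SimConfig(n_subjects=10000, seed=4))
        w = iptw_weights(data.X, data.treatment)
        keep = _full_rank_columns(data.X)
        smd = standardized_mean_differences(data.X[:, keep], data.treatment,
                                            w.weights)
        assert smd.max() < 0.1

    def test_perfect_separation_rejected(self):
        X = np.linspace(-1, 1, 100)[:, None]
        g = (X[:, 0] > 0).astype(int)
        with pytest.raises(ValueError, match="separation"):
            iptw_weights(X, g)


class TestKaplanMeier:
    def test_hand_computed_no_censoring(self):
        km = kaplan_meier([1, 2, 3, 4], [1, 1, 1, 1])
        assert km.evaluate(2.0) == pytest.approx(0.5, abs=1e-12)  # 3/4 * 2/3

    def test_all_censored_is_flat_one(self):
        km = kaplan_meier([3.0, 5.0], [0, 0])
        assert np.all(km.surv == 1.0)

    def test_weight_homogeneity(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10, 50)
        e = rng.integers(0, 2, 50)
        km1 = kaplan_meier(t, e)
        km2 = kaplan_meier(t, e, weights=2.0 * np.ones(50))
        assert np.allclose(km1.surv, km2.surv)

    def test_matches_lifelines_on_random_data(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(20, 300)
        c = rng.exponential(30, 300)
        obs, ev = np.minimum(t, c), (t <= c).astype(int)
        km = kaplan_meier(obs, ev)
        ref = KaplanMeierFitter().fit(obs, ev)
        theirs = ref.survival_function_at_times(km.times).to_numpy()
        assert np.allclose(km.surv, theirs, atol=1e-10)

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            kaplan_meier([1, 2], [1, 1], weights=[0.0, 0.0])


class TestLogrank:
    def test_identical_groups(self):
        chi2, p = logrank_test([1, 2, 3], [1, 1, 1], [1, 2, 3], [1, 1, 1])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_matches_lifelines_unweighted(self):
        rng = np.random.default_rng(4)
        ta, tb = rng.exponential(10, 120), rng.exponential(16, 130)
        ea = rng.integers(0, 2, 120)
        eb = rng.integers(0, 2, 130)
        ea[0] = eb[0] = 1
        chi2, p = logrank_test(ta, ea, tb, eb)
        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_power_under_strong_separation(self):
        rng = np.random.default_rng(5)
        ta = rng.exponential(10, 500)
        tb = rng.exponential(30, 500)  # hazard ratio 3
        _, p = logrank_test(ta, np.ones(500), tb, np.ones(500))
        assert p < 0.001

    def test_no_events_in_group_rejected(self):
        with pytest.raises(ValueError, match="events"):
            logrank_test([1, 2], [1, 1], [1, 2], [0, 0])


class TestCoxHr:
    def test_recovers_true_hazard_ratio(self):
        rng = np.random.default_rng(6)
        n = 2000
        g = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / np.where(g == 1, 0.005, 0.01))
        hr, ci, _ = cox_hr(t, np.ones(n), g)
        assert 0.42 <= hr <= 0.60
        assert ci[0] < hr < ci[1]

    def test_null_group_ci_covers_one(self):
        rng = np.random.default_rng(7)
        n = 800
        t = rng.exponential(10, n)
        g = rng.integers(0, 2, n)
        _, ci, _ = cox_hr(t, np.ones(n), g)
        assert ci[0] < 1.0 < ci[1]

    def test_matches_grid_maximization_on_tiny_data(self):
        """n<=5 oracle: the fitted coefficient maximizes the same partial
        likelihood as an exhaustive grid search."""
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        e = np.array([1, 1, 0, 1, 1])
        g = np.array([1, 0, 1, 0, 1])
        hr, _, _ = cox_hr(t, e, g)
        grid = np.linspace(-4, 4, 8001)
        vals = [cox_partial_loglik(b * g, t, e) for b in grid]
        best = grid[int(np.argmin(vals))]
        assert np.log(hr) == pytest.approx(best, abs=2e-3)


class TestBrier:
    @staticmethod
    def _const_curves(n, s):
        return [SurvivalCurve([0.0], [s]) for _ in range(n)]

    def test_oracle_predictions_score_zero(self):
        t = np.array([2.0, 4.0, 6.0])
        curves = [SurvivalCurve([ti], [0.0]) for ti in t]  # drop to 0 at death
        ibs = sb.integrated_brier(curves, t, np.ones(3), horizon=6.0)
        assert ibs == pytest.approx(0.0, abs=1e-12)

    def test_constant_half_scores_quarter(self):
        t = np.linspace(1, 10, 20)
        ibs = sb.integrated_brier(self._const_curves(20, 0.5), t,
                                  np.ones(20), horizon=10.0)
        assert ibs == pytest.approx(0.25, abs=1e-12)

    def test_matches_scikit_survival(self):
        from sksurv.metrics import brier_score as sk_brier
        rng = np.random.default_rng(8)
        n = 200
        t = rng.exponential(50, n)
        c = rng.exponential(80, n)
        obs, ev = np.minimum(t, c), (t <= c).astype(int)
        lam = rng.uniform(0.005, 0.05, n)
        grid_t = np.linspace(0.1, 200, 400)
        curves = [SurvivalCurve(grid_t, np.exp(-l * grid_t)) for l in lam]
        times = np.quantile(obs[ev == 1], [0.2, 0.4, 0.6])
        mine = brier_scores(curves, obs, ev, times)
        y = np.array([(bool(a), float(b)) for a, b in zip(ev, obs)],
                     dtype=[("e", bool), ("t", float)])
        preds = np.vstack([cu.evaluate(times) for cu in curves])
        _, theirs = sk_brier(y, y, preds, times)
        assert np.allclose(mine, theirs, atol=1e-12)

    def test_fitted_model_beats_permuted_predictions(self, snb_results,
                                                     het_cohort):
        test = het_cohort["test"]
        arm0 = test.arm(0)
        curves = snb_results.predict_survival(arm0.X, 0)
        h = min(120.0, arm0.time.max())
        fitted = sb.integrated_brier(curves, arm0.time, arm0.event, h)
        rng = np.random.default_rng(9)
        perm = [curves[i] for i in rng.permutation(len(curves))]
        shuffled = sb.integrated_brier(perm, arm0.time, arm0.event, h)
        assert fitted < shuffled

    def test_exhausted_censoring_distribution_rejected(self):
        # last subject censored: the censoring KM hits 0 at t=50, so IPCW
        # weights are undefined at the horizon
        t = np.array([1.0, 1.0, 1.0, 50.0])
        e = np.array([1, 1, 1, 0])
        curves = self._const_curves(4, 0.5)
        with pytest.raises(ValueError, match="horizon"):
            sb.integrated_brier(curves, t, e, horizon=50.0)


class TestTlearner:
    def test_null_effect_gives_balanced_recommendations(self):
        """With a truly null treatment effect the recommendations are noise.

        Per-subject recommendations are correlated through the shared
        coefficient estimates, so the fraction is averaged over independent
        cohorts rather than asserted on a single draw."""
        fracs, medians = [], []
        for seed in (10, 110, 210, 310, 410):
            cfg = sb.SimConfig(n_subjects=3000, seed=seed,
                               propensity_coefs=np.zeros(11),
                               propensity_intercept=0.0,
                               effect_coefs=np.zeros(11),
                               treatment_main_effect=0.0)
            data, _ = sb.generate_cohort(cfg)
            out = tlearner_cph(data, data)
            fracs.append(out["recommendation"].mean())
            medians.append(abs(np.median(out["ite"])))
        assert 0.3 < np.mean(fracs) < 0.7
        assert np.median(medians) < 15.0

    def test_deterministic(self, het_cohort):
        o1 = tlearner_cph(het_cohort["train"], het_cohort["test"])
        o2 = tlearner_cph(het_cohort["train"], het_cohort["test"])
        pd.testing.assert_frame_equal(o1, o2)


class TestRuleRecommender:
    def _frame(self, n=50):
        rng = np.random.default_rng(11)
        return pd.DataFrame({"x0": rng.normal(size=n),
                             "x1": rng.normal(size=n)})

    def test_always_treat(self):
        X = self._frame()
        rec = rule_recommender([{"recommend": 1}], X)
        assert (rec == 1).all()

    def test_disjoint_predicates_partition(self):
        X = self._frame()
        rules = [{"column": "x0", "op": ">", "value": 0.0, "recommend": 1},
                 {"column": "x0", "op": "<=", "value": 0.0, "recommend": 0}]
        rec = rule_recommender(rules, X)
        assert np.array_equal(rec, (X["x0"] > 0).astype(int))

    def test_unmatched_subjects_listed(self):
        X = self._frame(5)
        with pytest.raises(ValueError, match="no rule matched"):
            rule_recommender([{"column": "x0", "op": ">", "value": 100,
                               "recommend": 1}], X)

    def test_unknown_column_rejected(self):
        with pytest.raises(KeyError):
            rule_recommender([{"column": "zz", "op": ">", "value": 0,
                               "recommend": 1}], self._frame(3))


class TestEvaluateReport:
    def test_unit_weights_reproduce_unadjusted_exactly(self, het_cohort):
        test = het_cohort["test"]
        rec = (het_cohort["truth_test"]["ite"] > 0).astype(int).to_numpy()
        rep = evaluate(test, rec, None, n_bootstrap=20,
                       weights=np.ones(test.n), seed=0)
        assert rep.hr == rep.hr_iptw
        assert rep.hr_ci == rep.hr_iptw_ci
        assert rep.rd == rep.rd_iptw
        assert rep.drmst == rep.drmst_iptw
        assert rep.logrank_p == rep.logrank_p_iptw

    def test_invariant_to_subject_ordering(self, het_cohort):
        test = het_cohort["test"]
        rec = (het_cohort["truth_test"]["ite"] > 0).astype(int).to_numpy()
        rep1 = evaluate(test, rec, None, n_bootstrap=0, iptw=False, seed=0)
        perm = np.random.default_rng(12).permutation(test.n)
        rep2 = evaluate(test.subset(perm), rec[perm], None, n_bootstrap=0,
                        iptw=False, seed=0)
        assert rep1.hr == pytest.approx(rep2.hr, rel=1e-8)
        assert rep1.rd == pytest.approx(rep2.rd, abs=1e-9)
        assert rep1.drmst == pytest.approx(rep2.drmst, abs=1e-9)

    def test_bootstrap_cis_contain_point_estimates(self, snb_results,
                                                   het_cohort):
        test = het_cohort["test"]
        rec = snb_results.recommend(test)
        rep = evaluate(test, rec, snb_results, n_bootstrap=60, seed=1)
        assert rep.rd_ci[0] <= rep.rd <= rep.rd_ci[1]
        assert rep.drmst_ci[0] <= rep.drmst <= rep.drmst_ci[1]
        assert rep.ibs_arm0_ci[0] <= rep.ibs_arm0 <= rep.ibs_arm0_ci[1]
        assert rep.ibs_arm1_ci[0] <= rep.ibs_arm1 <= rep.ibs_arm1_ci[1]
        assert 0.0 <= rep.ibs_arm0 <= 1.0 and 0.0 <= rep.ibs_arm1 <= 1.0
        assert rep.hr > 0

    def test_single_group_rejected(self, het_cohort):
        test = het_cohort["test"]
        with pytest.raises(ValueError, match="non-empty"):
            evaluate(test, test.treatment, None)

    def test_report_serializes_to_plain_dict(self, het_cohort):
        test = het_cohort["test"]
        rec = (het_cohort["truth_test"]["ite"] > 0).astype(int).to_numpy()
        rep = evaluate(test, rec, None, n_bootstrap=15, seed=0)
        d = rep.to_dict()
        assert isinstance(d["hr"], float)
        assert isinstance(d["hr_ci"], list)
        assert "Recommendation effect" in rep.summary()
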