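"""Training loop mechanics: stopping rule, loss composition, linear limit,
hyperparameter tuning."""

import logging

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

import snbsurv as sb
from snbsurv.model import EarlyStopping, SNBConfig, SNBModel, snb_loss, tune
from snbsurv.snn import LayerSpec


class TestEarlyStopping:
    def test_strict_improvement_never_stops(self):
        es = EarlyStopping(patience=1000)
        losses = 10.0 - 0.001 * np.arange(5000)
        assert not any(es.update(i, losses[i]) for i in range(5000))

    def test_constant_loss_stops_exactly_patience_after_last_improvement(self):
        es = EarlyStopping(patience=1000)
        k = 37
        stopped_at = None
        for i in range(1, 5000):
            loss = 10.0 - 0.01 * min(i, k)  # improves until iteration k
            if es.update(i, loss):
                stopped_at = i
                break
        assert stopped_at == k + 1000
        assert es.best_iteration == k

    def test_patience_validation(self):
        with pytest.raises(ValueError):
            EarlyStopping(patience=0)


class TestLossComposition:
    @pytest.fixture()
    def small(self):
        data, _ = sb.generate_cohort(sb.SimConfig(n_subjects=200, seed=4))
        cfg = SNBConfig(seed=0, balance_weight=0.0, max_iterations=1,
                        patience=1)
        model = SNBModel(data, cfg)
        rngs = [np.random.default_rng(i) for i in range(3)]
        return data, model, model._build_networks(rngs)

    def test_zero_balance_weight_reduces_to_sum_of_cox_losses(self, small):
        data, model, (shared, risk0, risk1) = small
        cfg0 = SNBConfig(balance_weight=0.0)
        total = snb_loss(data, shared, risk0, risk1, cfg0)
        expected = 0.0
        Z = shared(data.X)
        for a, net in ((0, risk0), (1, risk1)):
            m = data.treatment == a
            expected += sb.cox_partial_loglik(net(Z[m]).ravel(),
                                              data.time[m], data.event[m])
        assert total == pytest.approx(expected, abs=1e-12)

    def test_balance_term_added_when_weight_positive(self, small):
        data, model, (shared, risk0, risk1) = small
        l0 = snb_loss(data, shared, risk0, risk1, SNBConfig(balance_weight=0.0))
        l1 = snb_loss(data, shared, risk0, risk1, SNBConfig(balance_weight=5.0))
        assert l1 > l0

    def test_event_free_arm_contributes_zero_with_warning(self, small, caplog):
        data, model, (shared, risk0, risk1) = small
        batch = data.subset(np.arange(30))
        batch.event[batch.treatment == 0] = 0
        with caplog.at_level(logging.WARNING, logger="snbsurv.model"):
            snb_loss(batch, shared, risk0, risk1, SNBConfig(balance_weight=0.0))
        assert any("zero events" in r.message for r in caplog.records)

    def test_single_arm_batch_skips_balance_with_warning(self, small, caplog):
        data, model, (shared, risk0, risk1) = small
        batch = data.arm(1)
        with caplog.at_level(logging.WARNING, logger="snbsurv.model"):
            snb_loss(batch, shared, risk0, risk1, SNBConfig(balance_weight=1.0))
        assert any("single-arm" in r.message for r in caplog.records)


class TestFit:
    def test_training_loss_finite_at_every_logged_iteration(self, tiny_fit):
        _, _, res = tiny_fit
        assert np.isfinite(res.training_log["train_loss"]).all()

    def test_fit_deterministic_given_seed(self, tiny_fit):
        data, cfg, res1 = tiny_fit
        res2 = SNBModel(data, cfg).fit()
        rec1 = res1.recommend(data)
        rec2 = res2.recommend(data)
        pd.testing.assert_frame_equal(rec1, rec2)
        for a in (0, 1):
            assert np.array_equal(res1.baselines[a][1], res2.baselines[a][1])

    def test_baseline_hazards_nondecreasing_from_zero(self, tiny_fit):
        _, _, res = tiny_fit
        for a in (0, 1):
            _, H = res.baselines[a]
            assert H[0] >= 0
            assert np.all(np.diff(H) >= 0)

    def test_linear_network_recovers_cox_coefficients(self):
        """With no balancing and purely linear layers the fitted scores must
        match a Newton-Raphson Cox fit per arm to within 0.1 per coefficient."""
        cfg = sb.SimConfig(n_subjects=2000, seed=6, censor_rate=0.0,
                           effect_coefs=np.zeros(11),
                           treatment_main_effect=0.0)
        data, _ = sb.generate_cohort(cfg)
        p = data.p
        mcfg = SNBConfig(
            shared_layers=[LayerSpec(p, "linear", 0.0)],
            risk_layers=[LayerSpec(1, "linear", 0.0)],
            balance_weight=0.0, learning_rate=5e-3, batch_size=512,
            max_iterations=3000, patience=3000, val_every=100, seed=0)
        res = SNBModel(data, mcfg).fit()
        mean, sd = res.scaler
        for a in (0, 1):
            arm = data.arm(a)
            # effective linear coefficients on the standardized scale
            eff = (res.shared.weights[0] @ res.risk[a].weights[0]).ravel()
            df = pd.DataFrame((arm.X - mean) / sd,
                              columns=[f"z{j}" for j in range(p)])
            # drop one reference level per one-hot block for identifiability
            keep = [j for j in range(p) if data.feature_names[j]
                    not in ("c0_lvl0", "c1_lvl0")]
            cph = CoxPHFitter()
            cph.fit(df.iloc[:, keep].assign(time=arm.time, event=arm.event),
                    duration_col="time", event_col="event")
            # compare per-covariate log hazard contrasts (network coefs are
            # identified only up to the one-hot null space, so compare the
            # continuous covariates, which are unambiguous)
            for k, j in enumerate(keep):
                if j >= 5:
                    continue
                assert eff[j] == pytest.approx(cph.params_.iloc[k], abs=0.1)

    def test_non_finite_loss_aborts_with_hint(self):
        data, _ = sb.generate_cohort(sb.SimConfig(n_subjects=200, seed=4))
        cfg = SNBConfig(seed=0, learning_rate=1e6, max_iterations=300,
                        patience=300, val_every=50, balance_weight=0.0)
        with pytest.raises(RuntimeError, match="learning_rate"):
            SNBModel(data, cfg).fit()

    def test_missing_arm_rejected(self):
        data, _ = sb.generate_cohort(sb.SimConfig(n_subjects=200, seed=4))
        only_treated = data.arm(1)
        with pytest.raises(ValueError, match="control arm"):
            SNBModel(only_treated, SNBConfig())


@pytest.fixture(scope="module")
def small_cohort():
    data, _ = sb.generate_cohort(sb.SimConfig(n_subjects=400, seed=8))
    return data


class TestTune:
    def _base(self):
        return SNBConfig(seed=5, cv_folds=2, max_iterations=30, patience=30,
                         val_every=10, batch_size=128, balance_weight=0.0)

    def test_single_point_grid_returned(self, small_cohort):
        best = tune(small_cohort, [{"learning_rate": 2e-3}], self._base())
        assert best.learning_rate == 2e-3

    def test_tie_broken_by_grid_order(self, small_cohort):
        # two identical points: strict argmin keeps the first
        best = tune(small_cohort, [{"learning_rate": 1e-3, "seed": 5},
                                   {"learning_rate": 1e-3, "seed": 5}],
                    self._base())
        assert best.learning_rate == 1e-3

    def test_selection_reproducible_across_runs(self, small_cohort):
        grid = [{"balance_weight": 0.0}, {"balance_weight": 10.0}]
        b1 = tune(small_cohort, grid, self._base())
        b2 = tune(small_cohort, grid, self._base())
        assert b1.balance_weight == b2.balance_weight

    def test_empty_grid_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="empty"):
            tune(small_cohort, [], self._base())


class TestCheckpoint:
    def test_save_load_roundtrip_preserves_predictions(self, tiny_fit, tmp_path):
        data, _, res = tiny_fit
        path = tmp_path / "model.snb"
        res.save(str(path))
        loaded = sb.SNBResults.load(str(path))
        rec1 = res.recommend(data.X)
        rec2 = loaded.recommend(data.X)
        pd.testing.assert_frame_equal(rec1, rec2)
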