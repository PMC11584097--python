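import dataclasses

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

import causalsurv as cs
from causalsurv.estimator import ShiftEstimate
from causalsurv.nn import MLP
from causalsurv.riskmodel import (RiskModelBundle, StepFunction,
                                  load_risk_model, save_risk_model)

from conftest import make_cohort_df
from oracles import breslow_bruteforce, cox_nll_bruteforce


@pytest.fixture
def ten_row_surv():
    # mixed censoring with a tied event time
    times = np.array([5.0, 3.0, 8.0, 3.0, 12.0, 7.0, 2.0, 9.0, 4.0, 6.0])
    events = np.array([1, 1, 0, 1, 1, 0, 1, 1, 0, 1])
    rng = np.random.default_rng(3)
    eta = rng.normal(size=10)
    return times, events, eta


class TestCoxPartialLikelihood:
    def test_matches_bruteforce_on_fixture(self, ten_row_surv):
        times, events, eta = ten_row_surv
        nll = cs.cox_partial_nll(eta, times, events)
        assert nll == pytest.approx(
            cox_nll_bruteforce(eta, times, events), abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_random(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        times = np.round(rng.uniform(1, 20, n), 0)  # force ties
        events = rng.integers(0, 2, n)
        if events.sum() == 0:
            events[0] = 1
        eta = rng.normal(size=n)
        nll, grad = cs.cox_partial_nll(eta, times, events, return_grad=True)
        assert nll == pytest.approx(
            cox_nll_bruteforce(eta, times, events), abs=1e-8)
        # gradient against central differences
        eps = 1e-6
        for j in range(0, n, 7):
            ep = eta.copy()
            ep[j] += eps
            em = eta.copy()
            em[j] -= eps
            num = (cs.cox_partial_nll(ep, times, events)
                   - cs.cox_partial_nll(em, times, events)) / (2 * eps)
            assert grad[j] == pytest.approx(num, abs=1e-6)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            cs.cox_partial_nll(np.zeros(3), np.ones(3), np.zeros(3))


class TestBreslowBaseline:
    def test_matches_bruteforce(self, ten_row_surv):
        times, events, eta = ten_row_surv
        h0 = cs.breslow_baseline(times, events, eta)
        for t in (0.0, 2.0, 5.5, 12.0, 20.0):
            assert h0(t) == pytest.approx(
                breslow_bruteforce(times, events, eta, t), abs=1e-12)
        assert h0(0.0) == 0.0
        grid = np.linspace(0, 20, 50)
        assert np.all(np.diff(h0(grid)) >= 0)

    def test_matches_lifelines_on_fixture(self):
        rng = np.random.default_rng(1)
        n = 80
        df = pd.DataFrame({
            "x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        df["time"] = np.round(rng.exponential(10, n) + 1, 1)
        df["event"] = rng.integers(0, 2, n)
        fitter = CoxPHFitter()
        fitter.fit(df, duration_col="time", event_col="event")
        # lifelines centers covariates; evaluate my Breslow on the same
        # centered linear predictor
        xc = df[["x1", "x2"]].to_numpy() - fitter._norm_mean.to_numpy()
        eta = xc @ fitter.params_.to_numpy()
        mine = cs.breslow_baseline(df["time"].to_numpy(),
                                   df["event"].to_numpy(), eta)
        theirs = fitter.baseline_cumulative_hazard_
        t_grid = theirs.index.to_numpy()
        np.testing.assert_allclose(mine(t_grid),
                                   theirs.iloc[:, 0].to_numpy(), atol=1e-6)


def _constant_class_bundle(log_hrs):
    """Bundle whose hazard depends only on the one-hot latent input."""
    k = len(log_hrs)
    net = MLP(k, (), 1, np.random.default_rng(0))
    net.layers[0].W[...] = np.asarray(log_hrs, dtype=float)[:, None]
    net.layers[0].b[...] = 0.0
    return RiskModelBundle(
        hazard_net=net, k_u=k, scaler_mean=np.zeros(15),
        scaler_sd=np.ones(15), baseline_times=np.array([1.0, 2.0]),
        baseline_cumhaz=np.array([0.1, 0.3]), latent_input=True,
        feature_input=False, trained=True)


class TestShiftAdjustedRisk:
    def test_hand_arithmetic_case(self):
        bundle = _constant_class_bundle(np.log([2.0, 0.5]))
        x = np.zeros((1, 15))
        post = np.array([[0.6, 0.4]])
        shift = ShiftEstimate(np.array([0.5, 0.5]), np.array([0.5, 0.5]),
                              np.array([0.5, 2.0]))
        r = cs.shift_adjusted_risk(bundle, x, post, shift)
        assert r[0] == pytest.approx(2.0 * 0.6 * 0.5 + 0.5 * 0.4 * 2.0,
                                     abs=1e-12)
        assert r[0] == pytest.approx(1.0, abs=1e-12)

    def test_unit_ratio_equals_unadjusted_mixture(self):
        rng = np.random.default_rng(0)
        bundle = _constant_class_bundle(rng.normal(size=3))
        x = np.zeros((20, 15))
        post = rng.dirichlet(np.ones(3), size=20)
        ones = ShiftEstimate.identity(3)
        r_adj = cs.shift_adjusted_risk(bundle, x, post, ones)
        hr = np.exp([bundle.log_hr(x[:1], np.eye(3)[i][None])[0]
                     for i in range(3)])
        np.testing.assert_allclose(r_adj, post @ hr, atol=1e-12)

    def test_single_class_is_identity(self):
        bundle = _constant_class_bundle([0.7])
        post = np.ones((4, 1))
        shift = ShiftEstimate(np.array([1.0]), np.array([1.0]),
                              np.array([1.0]))
        r = cs.shift_adjusted_risk(bundle, np.zeros((4, 15)), post, shift)
        np.testing.assert_allclose(r, np.exp(0.7))

    def test_mismatched_k_rejected(self):
        bundle = _constant_class_bundle([0.0, 0.0])
        shift = ShiftEstimate.identity(3)
        with pytest.raises(ValueError):
            cs.shift_adjusted_risk(bundle, np.zeros((1, 15)),
                                   np.array([[0.2, 0.3, 0.5]]), shift)

    def test_normalized_variant_reweights(self):
        bundle = _constant_class_bundle(np.log([2.0, 0.5]))
        post = np.array([[0.6, 0.4]])
        shift = ShiftEstimate(np.array([0.5, 0.5]), np.array([0.5, 0.5]),
                              np.array([0.5, 2.0]))
        r = cs.shift_adjusted_risk(bundle, np.zeros((1, 15)), post, shift,
                                   normalize=True)
        w = np.array([0.6 * 0.5, 0.4 * 2.0])
        w = w / w.sum()
        assert r[0] == pytest.approx(2.0 * w[0] + 0.5 * w[1], abs=1e-12)


def _single_class_config(seed):
    """One latent class: risk driven by features only, PH truth."""
    cfg = cs.two_class_shift_config(seed=seed, n_P=2000, n_Q=300)
    fl = np.zeros(15)
    fl[[0, 2, 5]] = [0.5, -0.4, 0.3]
    return dataclasses.replace(
        cfg, k_true=1, pi_P=np.array([1.0]), pi_Q=np.array([1.0]),
        class_feature_means=cfg.class_feature_means[:1],
        class_feature_sds=cfg.class_feature_sds[:1],
        stage_probs=cfg.stage_probs[:1],
        center_probs_P=cfg.center_probs_P[:1],
        center_probs_Q=cfg.center_probs_Q[:1],
        class_loghr=np.zeros(1), feature_loghr=fl, stage_effect=False,
        split_fractions=(0.5, 0.2, 0.3))


@pytest.fixture(scope="module")
def single_class_sim():
    cfg = _single_class_config(31)
    return cfg, cs.simulate_domain(cfg, "P")


class TestTrainRiskModel:
    def test_recovers_oracle_discrimination(self):
        # hazard net vs the generator's true linear predictor: mean
        # C-index shortfall below 0.03 across seeds
        diffs = []
        for seed in range(5):
            cfg = _single_class_config(100 + seed)
            sim = cs.simulate_domain(cfg, "P")
            train = sim.table.subset("internal-train")
            val = sim.table.subset("internal-val")
            test = sim.table.subset("internal-test")
            tc = cs.TrainingConfig(k_u=1, seed=seed, max_epochs=200,
                                   early_stopping_patience=30)
            bundle = cs.train_risk_model(
                train, np.ones((len(train), 1)), tc, val_cohort=val,
                val_latents_onehot=np.ones((len(val), 1)))
            scores = cs.predict(
                bundle, test, "unadjusted",
                latents_onehot=np.ones((len(test), 1)))["risk"]
            mask = np.asarray(sim.table.split == "internal-test")
            oracle = cs.concordance_index(test.time, test.event,
                                          sim.true_risk[mask])
            fitted = cs.concordance_index(test.time, test.event, scores)
            diffs.append(oracle - fitted)
        assert np.mean(diffs) < 0.03

    def test_constant_features_give_chance_cindex(self):
        df = make_cohort_df(n=60, seed=2)
        for j in range(15):
            df[f"feat_{j + 1}"] = 42.0
        table = cs.CohortTable(df)
        tc = cs.TrainingConfig(k_u=1, seed=0, max_epochs=5)
        bundle = cs.train_risk_model(table, np.ones((60, 1)), tc)
        scores = cs.predict(bundle, table, "unadjusted",
                            latents_onehot=np.ones((60, 1)))["risk"]
        assert np.allclose(scores, scores[0])
        assert cs.concordance_index(table.time, table.event, scores) == 0.5

    def test_zero_events_rejected(self):
        df = make_cohort_df(n=30, seed=3)
        df["event"] = 0
        table = cs.CohortTable(df)
        tc = cs.TrainingConfig(k_u=1)
        with pytest.raises(ValueError, match="event"):
            cs.train_risk_model(table, np.ones((30, 1)), tc)

    def test_misaligned_latents_rejected(self, single_class_sim):
        _, sim = single_class_sim
        tc = cs.TrainingConfig(k_u=1)
        with pytest.raises(ValueError, match="align"):
            cs.train_risk_model(sim.table, np.ones((3, 1)), tc)


@pytest.fixture(scope="module")
def fitted(single_class_sim):
    cfg, sim = single_class_sim
    tc = cs.TrainingConfig(k_u=1, seed=0, max_epochs=30)
    train = sim.table.subset("internal-train")
    bundle = cs.train_risk_model(train, np.ones((len(train), 1)), tc)
    return sim, bundle


class TestPredict:
    def test_survival_curve_boundary_and_monotonicity(self, fitted):
        sim, bundle = fitted
        out = cs.predict(bundle, sim.table, "unadjusted",
                         latents_onehot=np.ones((len(sim.table), 1)),
                         month_grid=np.arange(0, 61))
        s = out["survival"]
        np.testing.assert_allclose(s[:, 0], 1.0)
        assert np.all(np.diff(s, axis=1) <= 1e-12)
        assert np.all(np.isfinite(out["risk"]))

    def test_adjusted_without_shift_rejected(self, fitted):
        sim, bundle = fitted
        with pytest.raises(ValueError, match="Shift"):
            cs.predict(bundle, sim.table, "adjusted")

    def test_unknown_mode_rejected(self, fitted):
        sim, bundle = fitted
        with pytest.raises(ValueError):
            cs.predict(bundle, sim.table, "sideways")

    def test_checkpoint_round_trip(self, tmp_path, fitted):
        sim, bundle = fitted
        save_risk_model(bundle, tmp_path / "risk.json")
        back = load_risk_model(tmp_path / "risk.json")
        ones = np.ones((len(sim.table), 1))
        np.testing.assert_allclose(
            cs.predict(bundle, sim.table, "unadjusted",
                       latents_onehot=ones)["risk"],
            cs.predict(back, sim.table, "unadjusted",
                       latents_onehot=ones)["risk"])


class TestFinetune:
    def test_deterministic_and_non_degrading(self, separable_sim,
                                             trained_estimator):
        _, sim_p, _ = separable_sim
        tc, ae, est = trained_estimator
        train = sim_p.table.subset("internal-train")
        val = sim_p.table.subset("internal-val")
        latents = cs.assign_latents(ae, train)
        val_latents = cs.assign_latents(ae, val)
        bundle = cs.train_risk_model(train, latents.onehot, tc,
                                     val_cohort=val,
                                     val_latents_onehot=val_latents.onehot)
        before = cs.cox_partial_nll(
            bundle.log_hr(val.features, val_latents.onehot),
            val.time, val.event)
        b1 = cs.finetune_on_estimated_latents(
            dataclasses.replace(bundle), train, est, tc, val_cohort=val)
        after = cs.cox_partial_nll(
            b1.log_hr(val.features, val_latents.onehot),
            val.time, val.event)
        # estimator latents nearly match the AE's here: fine-tuning must
        # not noticeably degrade the validation partial likelihood
        assert after < before + 0.02
        b2 = cs.finetune_on_estimated_latents(
            dataclasses.replace(bundle), train, est, tc, val_cohort=val)
        np.testing.assert_array_equal(b1.hazard_net.layers[0].W,
                                      b2.hazard_net.layers[0].W)


class TestStepFunction:
    def test_zero_before_first_knot(self):
        f = StepFunction(np.array([2.0, 5.0]), np.array([0.3, 0.9]))
        np.testing.assert_allclose(f([0.0, 1.9, 2.0, 4.9, 5.0, 99.0]),
                                   [0.0, 0.0, 0.3, 0.3, 0.9, 0.9])
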