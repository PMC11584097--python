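import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import causalsurv as cs
from causalsurv.autoencoder import sample_gumbel, save_encoder, load_encoder

from oracles import cross_entropy_scalar, kl_uniform_scalar, mse_scalar


class TestGumbelSoftmax:
    def test_equal_logits_zero_noise_uniform(self):
        out = cs.gumbel_softmax(np.zeros(3), temperature=1.0,
                                noise=np.zeros(3))
        np.testing.assert_allclose(out, np.full(3, 1 / 3))

    def test_closed_form_two_logits(self):
        out = cs.gumbel_softmax(np.array([1.0, 0.0]), temperature=1.0,
                                noise=np.zeros(2))
        e = math.e
        np.testing.assert_allclose(out, [e / (e + 1), 1 / (e + 1)],
                                   atol=1e-12)

    def test_low_temperature_approaches_one_hot(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=5)
        noise = sample_gumbel(5, rng)
        out = cs.gumbel_softmax(logits, temperature=0.01, noise=noise)
        assert out.max() > 0.999
        assert out.argmax() == (logits + noise).argmax()

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            cs.gumbel_softmax(np.zeros(2), temperature=0.0, noise=np.zeros(2))

    @given(st.integers(0, 10_000), st.floats(0.01, 10.0))
    def test_simplex_property(self, seed, tau):
        rng = np.random.default_rng(seed)
        logits = rng.normal(scale=3.0, size=6)
        out = cs.gumbel_softmax(logits, temperature=tau, rng=rng)
        assert np.all(out >= 0)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)

    def test_entropy_nonincreasing_in_temperature(self):
        rng = np.random.default_rng(1)
        logits = rng.normal(size=4)
        noises = [sample_gumbel(4, rng) for _ in range(100)]

        def mean_entropy(tau):
            hs = []
            for g in noises:
                p = cs.gumbel_softmax(logits, tau, noise=g)
                hs.append(-np.sum(p * np.log(np.maximum(p, 1e-30))))
            return np.mean(hs)

        taus = [3.0, 1.0, 0.3, 0.1]
        ents = [mean_entropy(t) for t in taus]
        assert all(a >= b - 1e-9 for a, b in zip(ents, ents[1:]))


class TestCompositeLoss:
    def _random_batch(self, rng, n=8, k=4, d=6, n_c=3, n_w=5):
        return dict(
            x=rng.normal(size=(n, d)), x_hat=rng.normal(size=(n, d)),
            c=rng.integers(0, n_c, n), c_logits=rng.normal(size=(n, n_c)),
            w=rng.integers(0, n_w, n), w_logits=rng.normal(size=(n, n_w)),
            u_soft=rng.dirichlet(np.ones(k), size=n))

    def test_zero_weights_zero_total(self):
        rng = np.random.default_rng(0)
        batch = self._random_batch(rng)
        cfg = cs.TrainingConfig(beta_x=0, beta_c=0, beta_w=0, beta_kl=0)
        total, _ = cs.autoencoder_loss(config=cfg, **batch)
        assert total == 0.0

    def test_uniform_latent_zero_kld(self):
        rng = np.random.default_rng(1)
        batch = self._random_batch(rng, k=5)
        batch["u_soft"] = np.full((8, 5), 0.2)
        _, parts = cs.autoencoder_loss(config=cs.TrainingConfig(), **batch)
        assert parts["kld"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_case(self):
        # perfect reconstruction, confident correct heads, balanced
        # two-class batch mean: total reduces to the two tiny CE terms
        cfg = cs.TrainingConfig(k_u=2)
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        c = np.array([0, 1])
        c_logits = np.array([[10.0, -10.0], [-10.0, 10.0]])
        w = np.array([1, 0])
        w_logits = np.array([[-10.0, 10.0], [10.0, -10.0]])
        u_soft = np.array([[0.7, 0.3], [0.3, 0.7]])
        total, parts = cs.autoencoder_loss(x, x, c, c_logits, w, w_logits,
                                           u_soft, cfg)
        expected_ce = math.log(1 + math.exp(-20))
        assert parts["mse"] == 0.0
        assert parts["kld"] == pytest.approx(0.0, abs=1e-12)
        assert parts["ce_c"] == pytest.approx(expected_ce, rel=1e-9)
        assert total == pytest.approx(2 * expected_ce, rel=1e-9)

    @pytest.mark.parametrize("kld_mode", ["batch_mean", "per_sample"])
    def test_matches_scalar_oracles_and_weighted_sum(self, kld_mode):
        rng = np.random.default_rng(42)
        for _ in range(25):
            batch = self._random_batch(rng)
            betas = rng.uniform(0, 2, size=4)
            cfg = cs.TrainingConfig(beta_x=betas[0], beta_c=betas[1],
                                    beta_w=betas[2], beta_kl=betas[3],
                                    kld_mode=kld_mode)
            total, parts = cs.autoencoder_loss(config=cfg, **batch)
            k = batch["u_soft"].shape[1]
            assert parts["mse"] == pytest.approx(
                mse_scalar(batch["x"], batch["x_hat"]), abs=1e-6)
            assert parts["ce_c"] == pytest.approx(
                cross_entropy_scalar(batch["c_logits"], batch["c"]),
                abs=1e-6)
            assert parts["ce_w"] == pytest.approx(
                cross_entropy_scalar(batch["w_logits"], batch["w"]),
                abs=1e-6)
            if kld_mode == "batch_mean":
                expected_kld = kl_uniform_scalar(
                    batch["u_soft"].mean(axis=0), k)
            else:
                expected_kld = np.mean(
                    [kl_uniform_scalar(row, k) for row in batch["u_soft"]])
            assert parts["kld"] == pytest.approx(expected_kld, abs=1e-6)
            weighted = sum(b * parts[name] for b, name in
                           zip(betas, ["mse", "ce_c", "ce_w", "kld"]))
            assert total == pytest.approx(weighted, abs=1e-12)


class TestTraining:
    def test_recovers_latent_classes(self, separable_sim, trained_ae):
        # the uniform-prior KL biases class usage toward balance while the
        # truth is 80/20, so agreement is high but not perfect here; the
        # balanced three-class check below asserts the stronger bound
        _, sim_p, _ = separable_sim
        _, ae = trained_ae
        train = sim_p.table.subset("internal-train")
        truth = sim_p.u_true[np.asarray(sim_p.table.split
                                        == "internal-train")]
        hard = cs.assign_latents(ae, train).hard
        agreement = max(np.mean(hard == truth), np.mean(hard == 1 - truth))
        assert agreement > 0.85
        assert adjusted_rand_score(truth, hard) > 0.5

    def test_three_class_recovery(self):
        cfg = cs.default_multisite_config(seed=21)
        means = cfg.class_feature_means.copy()
        # pull centroids further apart so the classes are unambiguous
        base = means.mean(axis=0)
        means = base + 3.0 * (means - base)
        cfg = dataclasses.replace(cfg, class_feature_means=means, n_P=3000)
        sim = cs.simulate_domain(cfg, "P")
        tc = cs.TrainingConfig(k_u=3, seed=0, max_epochs=60)
        ae = cs.train_autoencoder(sim.table, tc)
        hard = cs.assign_latents(ae, sim.table).hard
        assert adjusted_rand_score(sim.u_true, hard) > 0.8

    def test_pure_autoencoder_beats_mean_predictor(self, separable_sim):
        _, sim_p, _ = separable_sim
        train = sim_p.table.subset("internal-train")
        tc = cs.TrainingConfig(k_u=2, seed=1, beta_c=0, beta_w=0, beta_kl=0,
                               max_epochs=40)
        ae = cs.train_autoencoder(train, tc)
        x = ae.standardize(train.features)
        u = cs.assign_latents(ae, train).soft
        mse = np.mean((ae.decoder(u) - x) ** 2)
        mse_of_mean = np.mean((x - x.mean(axis=0)) ** 2)
        assert mse <= mse_of_mean

    def test_training_is_deterministic(self, separable_sim):
        _, sim_p, _ = separable_sim
        full_train = sim_p.table.subset("internal-train")
        mask = np.zeros(len(full_train), dtype=bool)
        mask[:400] = True
        train = full_train.subset(mask)
        tc = cs.TrainingConfig(k_u=2, seed=7, max_epochs=10)
        a = cs.train_autoencoder(train, tc)
        b = cs.train_autoencoder(train, tc)
        assert a.history[-1]["loss"] == pytest.approx(
            b.history[-1]["loss"], abs=1e-9)
        np.testing.assert_array_equal(a.encoder.W, b.encoder.W)

    def test_kl_guards_prior_collapse(self):
        # uninformative features: with the KL term on, latent usage ends
        # closer to uniform than where it started
        rng = np.random.default_rng(0)
        from conftest import make_cohort_df
        df = make_cohort_df(n=600, seed=0)
        for j in range(15):
            df[f"feat_{j + 1}"] = rng.normal(50, 10, 600)
        table = cs.CohortTable(df)
        tc = cs.TrainingConfig(k_u=4, seed=2, beta_c=0, beta_w=0,
                               beta_kl=1.0, max_epochs=30)
        ae = cs.train_autoencoder(table, tc)
        from causalsurv.autoencoder import _kl_to_uniform
        usage = cs.assign_latents(ae, table).soft.mean(axis=0)
        init_rng = np.random.default_rng(tc.seed)
        from causalsurv.nn import Dense
        init_enc = Dense(15, 4, init_rng)
        x = ae.standardize(table.features)
        from causalsurv.nn import softmax
        init_usage = softmax(init_enc(x) / tc.temperature_end,
                             axis=1).mean(axis=0)
        assert _kl_to_uniform(usage, 4) < _kl_to_uniform(init_usage, 4)

    def test_single_center_disables_proxy_head(self):
        from conftest import make_cohort_df
        df = make_cohort_df(n=200, seed=1, n_centers=1)
        table = cs.CohortTable(df)
        tc = cs.TrainingConfig(k_u=2, seed=0, max_epochs=5)
        with pytest.warns(UserWarning, match="single center"):
            cs.train_autoencoder(table, tc)

    def test_empty_cohort_rejected(self, cohort):
        tc = cs.TrainingConfig()
        with pytest.raises(ValueError):
            cs.train_autoencoder(cohort.subset("external-test"), tc)


class TestAssignLatents:
    def test_untrained_state_rejected(self, trained_ae, cohort):
        _, ae = trained_ae
        broken = dataclasses.replace(ae, trained=False)
        with pytest.raises(RuntimeError):
            cs.assign_latents(broken, cohort)

    def test_deterministic_and_consistent(self, separable_sim, trained_ae):
        _, sim_p, _ = separable_sim
        _, ae = trained_ae
        a = cs.assign_latents(ae, sim_p.table)
        b = cs.assign_latents(ae, sim_p.table)
        np.testing.assert_array_equal(a.soft, b.soft)
        np.testing.assert_array_equal(a.hard, b.hard)
        np.testing.assert_array_equal(a.hard, a.soft.argmax(axis=1))
        assert np.all(a.onehot.sum(axis=1) == 1)

    def test_tie_break_lowest_index(self):
        # symmetric logits produce an exact tie: lowest index must win
        soft = np.array([[0.5, 0.5]])
        assert int(np.argmax(soft, axis=1)[0]) == 0

    def test_checkpoint_round_trip(self, tmp_path, separable_sim,
                                   trained_ae):
        _, sim_p, _ = separable_sim
        _, ae = trained_ae
        save_encoder(ae, tmp_path / "ae.json")
        back = load_encoder(tmp_path / "ae.json")
        a = cs.assign_latents(ae, sim_p.table)
        b = cs.assign_latents(back, sim_p.table)
        np.testing.assert_array_equal(a.hard, b.hard)
        np.testing.assert_allclose(a.soft, b.soft)
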