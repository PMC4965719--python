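import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_sae
from eegwords.sae import (
    SAEConfig,
    SAEModel,
    kl_sparsity,
    reconstruction_loss,
    sae_cost,
    sae_gradient,
    sigmoid,
    train_sae,
)


def naive_forward(model, x):
    """Straight-line re-evaluation of the encode/decode maps as the oracle."""
    a = np.asarray(x, dtype=float)
    for W, b in model.encoder + model.decoder:
        a = np.array([1.0 / (1.0 + math.exp(-(W[j] @ a + b[j]))) for j in range(len(b))])
    return a


def finite_difference_grads(model, X, eps=1e-6):
    out = []
    for W, b in model.encoder + model.decoder:
        for p in (W, b):
            g = np.zeros_like(p)
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                old = p[i]
                p[i] = old + eps
                jp = sae_cost(model, X)[0]
                p[i] = old - eps
                jm = sae_cost(model, X)[0]
                p[i] = old
                g[i] = (jp - jm) / (2 * eps)
            out.append(g)
    return out


class TestPrimitives:
    def test_sigmoid_values(self):
        assert sigmoid(0.0) == 0.5
        assert sigmoid(1.0) == pytest.approx(0.7310585786300049, abs=1e-12)
        assert sigmoid(1000.0) == 1.0  # saturates without overflow
        assert sigmoid(-1000.0) == 0.0

    def test_reconstruction_loss_values(self):
        d = 7
        x = np.full(d, 0.5)
        assert reconstruction_loss(x, x) == pytest.approx(d * math.log(2), rel=1e-12)
        assert reconstruction_loss([1.0, 0.0], [0.8, 0.3]) == pytest.approx(
            0.5798184952530422, abs=1e-12
        )
        # perfect hard reconstruction drives the loss to ~0 (epsilon clamp)
        assert reconstruction_loss([1.0, 0.0], [1.0, 0.0]) < 1e-8
        with pytest.raises(ValueError):
            reconstruction_loss([0.5], [0.5, 0.5])

    def test_kl_sparsity_values(self):
        assert kl_sparsity(0.05, [0.05, 0.05]) == pytest.approx(0.0, abs=1e-15)
        assert kl_sparsity(0.5, [0.25]) == pytest.approx(0.14384103622589044, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        rho=st.floats(0.01, 0.99),
        rho_hat=st.lists(st.floats(0.001, 0.999), min_size=1, max_size=8),
    )
    def test_kl_nonnegative(self, rho, rho_hat):
        assert kl_sparsity(rho, rho_hat) >= 0.0


class TestEncodeDecode:
    def test_zero_parameters_give_half(self):
        m = random_sae(0, 6, [4])
        for W, b in m.encoder + m.decoder:
            W[:] = 0.0
            b[:] = 0.0
        np.testing.assert_array_equal(m.encode(np.zeros(6)), np.full(4, 0.5))
        np.testing.assert_array_equal(m.decode(np.zeros(4)), np.full(6, 0.5))

    def test_cancellation(self):
        m = random_sae(0, 1, [1])
        m.encoder[0][0][:] = 2.0
        m.encoder[0][1][:] = -2.0
        assert m.encode(np.array([1.0]))[0] == 0.5

    @pytest.mark.parametrize("hidden", [[4], [5, 3]])
    def test_matches_naive_oracle(self, hidden):
        m = random_sae(3, 6, hidden)
        x = np.random.default_rng(4).random(6)
        np.testing.assert_allclose(m.reconstruct(x), naive_forward(m, x), rtol=1e-12)

    def test_shape_errors(self):
        m = random_sae(0, 6, [4])
        with pytest.raises(ValueError):
            m.encode(np.zeros(5))
        with pytest.raises(ValueError):
            m.decode(np.zeros(6))

    def test_reconstruction_in_open_unit_interval(self):
        m = random_sae(5, 8, [4, 3])
        x = np.random.default_rng(6).random(8)
        r = m.reconstruct(x)
        assert np.all((r > 0) & (r < 1))


class TestCost:
    def test_beta_zero_collapses_to_plain_cost(self):
        m = random_sae(1, 6, [4])
        X = np.random.default_rng(2).random((5, 6))
        j_sae, j_ae, _ = sae_cost(m, X, beta=0.0)
        assert j_sae == j_ae

    def test_matches_per_item_oracle(self):
        m = random_sae(2, 6, [4])
        X = np.random.default_rng(3).random((5, 6))
        j_sae, j_ae, rho_hat = sae_cost(m, X)
        oracle_ae = sum(reconstruction_loss(x, naive_forward(m, x)) for x in X)
        assert j_ae == pytest.approx(oracle_ae, rel=1e-10)
        oracle_rho = np.mean([m.encode(x) for x in X], axis=0)
        np.testing.assert_allclose(rho_hat, oracle_rho, rtol=1e-12)
        assert j_sae == pytest.approx(
            oracle_ae + m.config.beta * kl_sparsity(m.config.rho, oracle_rho), rel=1e-10
        )

    def test_empty_batch_rejected(self):
        m = random_sae(0, 6, [4])
        with pytest.raises(ValueError):
            sae_cost(m, np.empty((0, 6)))


class TestGradient:
    @pytest.mark.parametrize("hidden", [[4], [4, 3]])
    def test_matches_finite_differences(self, hidden):
        m = random_sae(9, 6, hidden)
        X = np.random.default_rng(10).random((5, 6))
        enc_g, dec_g = sae_gradient(m, X)
        analytic = [g for pair in enc_g + dec_g for g in pair]
        numeric = finite_difference_grads(m, X)
        for a, n in zip(analytic, numeric):
            scale = max(np.max(np.abs(n)), 1e-8)
            assert np.max(np.abs(a - n)) / scale < 1e-6

    def test_beta_zero_equals_plain_autoencoder_gradient(self):
        m = random_sae(4, 6, [4])
        X = np.random.default_rng(5).random((4, 6))
        g_sparse = sae_gradient(m, X, beta=0.0)
        m2 = SAEModel(m.encoder, m.decoder,
                      SAEConfig(input_dim=6, hidden_dims=[4], beta=0.0))
        g_plain = sae_gradient(m2, X)
        for (a, b), (c, d) in zip(g_sparse[0] + g_sparse[1], g_plain[0] + g_plain[1]):
            np.testing.assert_array_equal(a, c)
            np.testing.assert_array_equal(b, d)


class TestTraining:
    def sinusoid_batch(self, n=200, d=32, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(d) / d
        X = np.stack([
            0.5 + 0.4 * np.sin(2 * np.pi * rng.uniform(1, 4) * t + rng.uniform(0, 6.3))
            for _ in range(n)
        ])
        return X

    def test_deterministic_given_seed(self):
        X = self.sinusoid_batch()
        cfg = SAEConfig(input_dim=32, hidden_dims=[8, 4], epochs=2, seed=42)
        m1, _ = train_sae(X, cfg)
        m2, _ = train_sae(X, cfg)
        for (a, b), (c, d) in zip(m1.encoder + m1.decoder, m2.encoder + m2.decoder):
            np.testing.assert_array_equal(a, c)
            np.testing.assert_array_equal(b, d)

    def test_training_reduces_reconstruction_cost(self):
        X = self.sinusoid_batch()
        cfg = SAEConfig(input_dim=32, hidden_dims=[10], epochs=30,
                        learning_rate=0.5, seed=1)
        _, stats = train_sae(X, cfg)
        log = stats.of_phase("finetune")
        assert log[-1]["J_AE"] < log[0]["J_AE"]

    def test_cost_decomposition_identity_every_epoch(self, trained_sae):
        _, stats = trained_sae
        for r in stats.records:
            assert r["J_SAE"] == pytest.approx(r["J_AE"] + r["penalty"], rel=1e-9)

    def test_sparsity_pressure_pulls_activations_toward_target(self):
        """With a heavy penalty the mean top-layer activation approaches rho."""
        X = np.random.default_rng(3).random((64, 16))
        cfg = SAEConfig(input_dim=16, hidden_dims=[8], rho=0.05, beta=20.0,
                        epochs=60, learning_rate=0.5, seed=2)
        model, stats = train_sae(X, cfg)
        first = stats.of_phase("pretrain1")[0]["mean_rho_hat"]
        last = stats.of_phase("finetune")[-1]["mean_rho_hat"]
        assert abs(last - 0.05) < abs(first - 0.05)
        assert last < 0.15

    def test_config_validation(self):
        SAEConfig(input_dim=768, hidden_dims=[250])
        SAEConfig(input_dim=768, hidden_dims=[400, 250])
        with pytest.raises(ValueError):
            SAEConfig(input_dim=768, hidden_dims=[400, 250, 100])
        with pytest.raises(ValueError):
            SAEConfig(input_dim=10, hidden_dims=[20])

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            train_sae(np.zeros((40, 5)), SAEConfig(input_dim=6, hidden_dims=[3]))

    def test_overfit_single_vector(self):
        """An overcomplete net fit to one repeated vector reconstructs it."""
        rng = np.random.default_rng(8)
        x = rng.random(12)
        X = np.tile(x, (16, 1))
        cfg = SAEConfig(input_dim=12, hidden_dims=[12], beta=0.0, epochs=400,
                        learning_rate=1.0, batch_size=16, seed=3)
        model, _ = train_sae(X, cfg)
        assert np.max(np.abs(model.reconstruct(x) - x)) < 0.05


class TestPersistence:
    def test_save_load_round_trip(self, trained_sae, tmp_path):
        model, _ = trained_sae
        path = tmp_path / "sae.model"
        model.save(path)
        back = model.load(path)
        assert back.config == model.config
        x = np.random.default_rng(0).random(model.config.input_dim)
        np.testing.assert_array_equal(back.reconstruct(x), model.reconstruct(x))

    def test_save_is_byte_deterministic(self, trained_sae, tmp_path):
        model, _ = trained_sae
        model.save(tmp_path / "a")
        model.save(tmp_path / "b")
        assert (tmp_path / "a").read_bytes() == (tmp_path / "b").read_bytes()
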