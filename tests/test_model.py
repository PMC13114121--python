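"""Network contracts: shapes, determinism, attention algebra, loss identities."""

import numpy as np
import pytest

import priorvae as pv
from priorvae import nn
from priorvae.model import (
    NetworkConfig,
    PriorFusionVAE,
    classification_loss,
    kl_loss,
    load_checkpoint,
    reconstruction_loss,
    save_checkpoint,
    total_loss,
)


@pytest.fixture
def model(tiny_config, tiny_prior):
    return PriorFusionVAE(tiny_config, tiny_prior)


RNG = np.random.default_rng(100)


class TestEncodeClassify:
    def test_shapes_and_ranges(self, model):
        x = RNG.standard_normal((4, 9))
        out = model.eval_mode().forward(x)
        assert out["mu"].shape == (4, 8)
        assert out["x_recon"].shape == (4, 9)
        assert 0 < out["x_recon"].data.min() and out["x_recon"].data.max() < 1
        probs = out["y_hat"].data
        assert np.all((probs > 0) & (probs < 1))

    def test_inference_pointwise_and_deterministic(self, model):
        model.eval_mode()
        x = RNG.standard_normal((1, 9))
        dup = np.vstack([x, x])
        out = model.classify(model.encode(nn.Tensor(dup))).data
        assert out[0] == out[1]
        again = model.classify(model.encode(nn.Tensor(dup))).data
        np.testing.assert_array_equal(out, again)

    def test_dimension_mismatch(self, model):
        with pytest.raises(ValueError, match="width"):
            model.encode(np.zeros((2, 5)))

    def test_zeroed_final_layer_gives_half(self, model):
        model.eval_mode()
        model.cls3.weight.data[:] = 0
        model.cls3.bias.data[:] = 0
        p = model.predict_proba(RNG.standard_normal((3, 9)))
        np.testing.assert_allclose(p, 0.5)


class TestReparameterize:
    def test_eval_mode_noise_free(self, model):
        model.eval_mode()
        mu = nn.Tensor(RNG.standard_normal((5, 8)))
        z, eps = model.reparameterize(mu)
        np.testing.assert_array_equal(z.data, mu.data)
        assert not eps.any()

    def test_seeded_reproducibility(self, model):
        model.train_mode()
        mu = nn.Tensor(np.zeros((3, 8)))
        z1, _ = model.reparameterize(mu, np.random.default_rng(5))
        z2, _ = model.reparameterize(mu, np.random.default_rng(5))
        np.testing.assert_array_equal(z1.data, z2.data)

    def test_noise_moments(self, model):
        model.train_mode()
        mu = nn.Tensor(np.zeros((10_000, 8)))
        z, _ = model.reparameterize(mu, np.random.default_rng(6))
        noise = z.data - mu.data
        assert abs(noise.mean()) < 0.05
        assert abs(noise.var() - 1) < 0.05


class TestAttention:
    def test_prior_projection_shape_and_linearity(self, model):
        rp = model.project_prior()
        assert rp.shape == (5, 8)
        model.prior_proj.weight.data[:] = 0
        model.prior_proj.bias.data[:] = 0
        np.testing.assert_array_equal(model.project_prior().data, 0)

    def test_weights_are_probability_rows(self, model):
        mu = nn.Tensor(RNG.standard_normal((6, 8)))
        model.attend(mu, model.project_prior())
        w = model.last_attention_weights  # (H, B, P)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(w >= 0)

    def test_single_prior_row_closed_form(self, tiny_config):
        """P=1: softmax over one key is 1, so the pre-normalization output is
        (R'Wv per head, concatenated) @ Wo for every sample."""
        prior = pv.PriorMatrix(["p0"], RNG.standard_normal((1, 12)))
        m = PriorFusionVAE(tiny_config, prior)
        mu = nn.Tensor(RNG.standard_normal((4, 8)))
        rp = m.project_prior()
        a = m.attend(mu, rp)
        heads = np.concatenate([rp.data @ Wv.data for Wv in m.Wv], axis=1)
        expected_pre = heads @ m.Wo.data           # 1 x d, same for every sample
        pre = np.tile(expected_pre, (4, 1))
        xhat = (pre - pre.mean(axis=1, keepdims=True)) / np.sqrt(
            pre.var(axis=1, keepdims=True) + 1e-5)
        np.testing.assert_allclose(a.data, xhat * m.attn_ln.gamma.data + m.attn_ln.beta.data,
                                   atol=1e-10)

    def test_prior_row_permutation_invariance(self, tiny_config, tiny_prior):
        m1 = PriorFusionVAE(tiny_config, tiny_prior)
        perm = [3, 0, 4, 1, 2]
        prior_p = pv.PriorMatrix([tiny_prior.protein_ids[i] for i in perm],
                                 tiny_prior.values[perm])
        m2 = PriorFusionVAE(tiny_config, prior_p)
        mu = nn.Tensor(RNG.standard_normal((3, 8)))
        a1 = m1.attend(mu, m1.project_prior()).data
        a2 = m2.attend(mu, m2.project_prior()).data
        np.testing.assert_allclose(a1, a2, atol=1e-10)


class TestFuse:
    def test_endpoints_and_arithmetic(self, model):
        z = nn.Tensor(np.array([[1.0, 0.0, 0.0]]))
        a = nn.Tensor(np.array([[0.0, 1.0, 0.0]]))
        model.config.fusion_lambda = 1.0
        np.testing.assert_array_equal(model.fuse(z, a).data, z.data)
        model.config.fusion_lambda = 0.7
        np.testing.assert_allclose(model.fuse(z, a).data, [[0.7, 0.3, 0.0]])

    def test_fixed_point(self, model):
        z = nn.Tensor(RNG.standard_normal((2, 8)))
        np.testing.assert_allclose(model.fuse(z, z).data, z.data)


class TestLosses:
    def test_reconstruction_hand_values(self):
        assert reconstruction_loss(np.array([[1.0, 1.0]]), np.zeros((1, 2))).data == 2.0
        assert reconstruction_loss(np.array([[1, 1], [3, 0]]), np.zeros((2, 2))).data == 5.5
        assert reconstruction_loss(np.ones((3, 4)), np.ones((3, 4))).data == 0.0

    def test_kl_hand_values(self):
        assert kl_loss(np.zeros((2, 3))).data == 0.0
        assert kl_loss(np.array([[1.0, 1.0]])).data == 1.0
        assert kl_loss(np.array([[1, 1], [3, 0]])).data == 2.75
        assert kl_loss(np.array([[1, 1], [3, 0]]), reduction="sum").data == 5.5

    def test_classification_hand_values(self):
        assert classification_loss(np.array([0.5]), np.array([1.0])).data == pytest.approx(np.log(2))
        near = classification_loss(np.array([1.0 - 1e-9]), np.array([1.0]))
        assert near.data < 1e-5  # clamped, near zero
        both = classification_loss(np.array([0.5, 0.5]), np.array([1.0, 0.0]))
        assert both.data == pytest.approx(np.log(2))

    def test_total_weighted_sum_and_breakdown(self):
        tot, parts = total_loss(2.0, 2.75, 0.6931, lambda_rec=0.1, lambda_kl=0.2)
        assert parts.total == pytest.approx(1.4431)
        assert parts.total == pytest.approx(
            0.1 * parts.reconstruction + 0.2 * parts.kl + parts.classification, abs=1e-6)
        tot0, _ = total_loss(0.0, 0.0, 0.0)
        assert tot0.data == 0.0
        totc, _ = total_loss(9.0, 9.0, 0.5, lambda_rec=0.0, lambda_kl=0.0)
        assert totc.data == 0.5


class TestTrainingContracts:
    def test_prior_bit_identical_after_training_steps(self, tiny_config, tiny_prior):
        m = PriorFusionVAE(tiny_config, tiny_prior)
        before = m.prior.data.copy()
        opt = nn.Adam(m.parameters(), lr=1e-2)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((6, 9))
        y = np.array([1, 0, 1, 0, 1, 0], float)
        for _ in range(3):
            opt.zero_grad()
            loss, _ = m.batch_loss(x, x, y, rng)
            loss.backward()
            opt.step()
        np.testing.assert_array_equal(m.prior.data, before)

    def test_loss_breakdown_identity_during_training(self, tiny_config, tiny_prior):
        m = PriorFusionVAE(tiny_config, tiny_prior)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((4, 9))
        _, parts = m.batch_loss(x, x, np.array([1, 0, 0, 1], float), rng)
        assert parts.total == pytest.approx(
            0.1 * parts.reconstruction + 0.2 * parts.kl + parts.classification, abs=1e-6)

    def test_checkpoint_round_trip(self, tiny_config, tiny_prior, tmp_path):
        m = PriorFusionVAE(tiny_config, tiny_prior)
        m.eval_mode()
        x = RNG.standard_normal((3, 9))
        p = m.predict_proba(x)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(m, path)
        back = load_checkpoint(path).eval_mode()
        np.testing.assert_array_equal(back.predict_proba(x), p)

    def test_config_invariants(self):
        with pytest.raises(ValueError, match="divisible"):
            NetworkConfig(input_dim=10, latent_dim=10, n_heads=4)
        with pytest.raises(ValueError, match="fusion_lambda"):
            NetworkConfig(input_dim=10, fusion_lambda=1.5)


class TestAblationSanityFloor:
    def test_reduces_to_mlp_on_separable_data(self, small_prior):
        """With reconstruction and KL off and fusion at lambda=1 the model is
        an MLP classifier on mu and must separate linearly separable classes
        (Gaussian features, 2-SD mean shift)."""
        from priorvae.io import AbundanceMatrix, LabelTable

        rng = np.random.default_rng(21)
        n, m = 200, 30
        y = np.zeros(n, int)
        y[rng.permutation(n)[:80]] = 1
        X = rng.standard_normal((n, m))
        X[y == 1, :6] += 2.0
        X -= X.min()  # non-negative, separability unchanged
        am = AbundanceMatrix([f"s{i}" for i in range(n)], [f"f{j}" for j in range(m)], X)
        cfg = pv.NetworkConfig(input_dim=30, latent_dim=32, hidden_dim=32, n_heads=4,
                               classifier_dims=(16, 8), lambda_rec=0.0, lambda_kl=0.0,
                               fusion_lambda=1.0, seed=42)
        settings = pv.TrainSettings(epochs=60, seed=42)
        res = pv.run_cv(am, LabelTable(am.sample_ids, y), small_prior, cfg, settings)
        assert res.mean_auc >= 0.95
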