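"""Architecture contracts: shapes, conditioning identities, determinism."""

import numpy as np
import pytest

from cardisent import losses as L
from cardisent.networks import (
    DisentangleNets,
    FilmDecoder,
    NetConfig,
    SentiencyCode,
    SpadeNorm,
    film_modulate,
)
from cardisent.nn import EvoNormProjection, Tensor

CFG = NetConfig(base_filters=8, seg_width=16, disc_filters=8)


@pytest.fixture(scope="module")
def nets():
    return DisentangleNets(CFG, seed=0)


@pytest.fixture(scope="module")
def batch():
    rng = np.random.default_rng(0)
    return Tensor(rng.uniform(0, 1, (2, 1, 32, 32)).astype(np.float32))


class TestSkeletonEncoder:
    def test_factor_has_eight_channels_image_sized(self, nets, batch):
        factor = nets.skeleton(batch)
        assert factor.soft.shape == (2, 8, 32, 32)
        assert factor.hard.shape == (2, 8, 32, 32)

    def test_hard_factor_binary_with_nonzero_gradients(self, nets, batch):
        nets.train()
        factor = nets.skeleton(batch)
        assert set(np.unique(factor.hard.data)) <= {0.0, 1.0}
        factor.hard.sum().backward()
        norms = [np.abs(p.grad).sum() for p in nets.skeleton.parameters()
                 if p.grad is not None]
        assert sum(n > 0 for n in norms) > 0
        nets.eval()

    def test_indivisible_size_rejected(self, nets):
        with pytest.raises(ValueError):
            nets.skeleton(Tensor(np.zeros((1, 1, 30, 30), dtype=np.float32)))


class TestSentiencyEncoder:
    def test_forced_zero_eps_returns_mu(self, nets, batch):
        nets.train()
        factor = nets.skeleton(batch)
        code = nets.sentiency(batch, factor, eps=np.zeros((2, 8), np.float32))
        np.testing.assert_allclose(code.z.data, code.mu.data, atol=1e-7)
        nets.eval()

    def test_unit_eps_shifts_by_sigma(self, nets, batch):
        nets.train()
        factor = nets.skeleton(batch)
        eps = np.ones((2, 8), dtype=np.float32)
        code = nets.sentiency(batch, factor, eps=eps)
        sigma = np.exp(code.logvar.data / 2)
        np.testing.assert_allclose(code.z.data, code.mu.data + sigma, atol=1e-6)
        nets.eval()

    def test_eval_mode_deterministic(self, nets, batch):
        nets.eval()
        factor = nets.skeleton(batch)
        a = nets.sentiency(batch, factor).z.data
        b = nets.sentiency(batch, factor).z.data
        np.testing.assert_array_equal(a, b)


class TestFilm:
    def test_identity_modulation(self):
        f = Tensor(np.random.default_rng(0).random((1, 3, 4, 4)).astype(np.float32))
        out = film_modulate(f, np.ones((1, 3), np.float32),
                            np.zeros((1, 3), np.float32))
        np.testing.assert_allclose(out.data, f.data, atol=1e-7)

    def test_zero_gamma_yields_beta(self):
        f = Tensor(np.ones((1, 2, 2, 2), dtype=np.float32))
        beta = np.array([[0.3, -0.2]], dtype=np.float32)
        out = film_modulate(f, np.zeros((1, 2), np.float32), beta)
        np.testing.assert_allclose(out.data[0, 0], 0.3, atol=1e-7)
        np.testing.assert_allclose(out.data[0, 1], -0.2, atol=1e-7)

    def test_scalar_arithmetic(self):
        f = Tensor(np.full((1, 1, 1, 1), 0.5, dtype=np.float32))
        out = film_modulate(f, np.full((1, 1), 2.0, np.float32),
                            np.full((1, 1), -1.0, np.float32))
        assert out.data.item() == pytest.approx(0.0)

    def test_shape_mismatch_rejected(self):
        f = Tensor(np.zeros((1, 3, 4, 4), dtype=np.float32))
        with pytest.raises(ValueError):
            film_modulate(f, np.ones((1, 2), np.float32),
                          np.zeros((1, 2), np.float32))

    def test_forced_identity_predictor_reduces_to_plain_stack(self, nets, batch):
        """With the gamma-beta predictor forced to (1, 0) the decoder is an
        unconditioned convolution stack: its output no longer depends on z."""
        nets.eval()
        factor = nets.skeleton(batch)
        fresh = FilmDecoder(CFG, rng=np.random.default_rng(1))
        fresh.eval()
        fresh.pred_out.weight.data[:] = 0.0
        fresh.pred_out.bias.data[:] = 0.0
        rng = np.random.default_rng(2)
        z1 = Tensor(rng.normal(size=(2, 8)).astype(np.float32))
        z2 = Tensor(rng.normal(size=(2, 8)).astype(np.float32))
        gammas, betas = fresh.predict_gamma_beta(z1)
        for g, b in zip(gammas, betas):
            np.testing.assert_allclose(g.data, 1.0, atol=1e-7)
            np.testing.assert_allclose(b.data, 0.0, atol=1e-7)
        code1 = SentiencyCode(mu=z1, logvar=z1, z=z1, eps=None)
        code2 = SentiencyCode(mu=z2, logvar=z2, z=z2, eps=None)
        out1, _ = fresh(factor, code1)
        out2, _ = fresh(factor, code2)
        np.testing.assert_allclose(out1.data, out2.data, atol=1e-6)

    def test_decoder_output_shapes(self, nets, batch):
        nets.eval()
        factor = nets.skeleton(batch)
        code = nets.sentiency(batch, factor)
        final, penult = nets.film(factor, code)
        assert final.shape == (2, 1, 32, 32)
        assert penult.shape == (2, 8, 32, 32)


class TestSpade:
    def _setup(self):
        rng = np.random.default_rng(0)
        norm = SpadeNorm(4, CFG, rng=rng)
        norm.eval()
        f_in = Tensor(rng.normal(size=(2, 4, 16, 16)).astype(np.float32))
        soft = Tensor(rng.uniform(0, 1, (2, 8, 16, 16)).astype(np.float32))
        from cardisent.networks import SpatialFactor

        factor = SpatialFactor(soft=soft, hard=soft.round_ste())
        z = Tensor(rng.normal(size=(2, 8)).astype(np.float32))
        return norm, f_in, factor, z

    def test_unit_modulation_returns_instance_normalized_input(self):
        norm, f_in, factor, z = self._setup()
        # force gamma(f_SK) == 1, beta(f_SK) == 0 and identity z-modulation
        norm.z_mod.weight.data[:] = 0
        norm.z_mod.bias.data[:] = 0
        norm.head_gamma.weight.data[:] = 0
        norm.head_gamma.bias.data[:] = 1
        norm.head_beta.weight.data[:] = 0
        norm.head_beta.bias.data[:] = 0
        out = norm(f_in, factor, z).data
        mu = f_in.data.mean(axis=(2, 3), keepdims=True)
        sd = np.sqrt(f_in.data.var(axis=(2, 3), keepdims=True) + norm.eps)
        np.testing.assert_allclose(out, (f_in.data - mu) / sd, atol=1e-5)

    def test_constant_input_returns_beta_of_factor(self):
        norm, _, factor, z = self._setup()
        norm.z_mod.weight.data[:] = 0
        norm.z_mod.bias.data[:] = 0
        const = Tensor(np.full((2, 4, 16, 16), 3.0, dtype=np.float32))
        out = norm(const, factor, z)
        shared = norm.shared(factor.hard).relu()
        beta = norm.head_beta(shared)
        np.testing.assert_allclose(out.data, beta.data, atol=1e-4)

    def test_channel_permutation_changes_output(self):
        norm, f_in, factor, z = self._setup()
        out = norm(f_in, factor, z).data
        from cardisent.networks import SpatialFactor

        perm = factor.hard.data[:, ::-1].copy()
        factor_perm = SpatialFactor(soft=Tensor(perm), hard=Tensor(perm))
        out_perm = norm(f_in, factor_perm, z).data
        assert not np.allclose(out, out_perm)

    def test_decoder_image_sized_and_style_sensitive(self, nets, batch):
        nets.eval()
        factor = nets.skeleton(batch)
        code = nets.sentiency(batch, factor)
        feats = nets.spade(code, factor)
        assert feats.shape[-2:] == (32, 32)
        other = SentiencyCode(mu=code.mu, logvar=code.logvar,
                              z=code.z + 2.0, eps=None)
        feats2 = nets.spade(other, factor)
        assert not np.allclose(feats.data, feats2.data)


class TestReconstructorSegmentorDiscriminator:
    def test_reconstruction_in_unit_range_image_shaped(self, nets, batch):
        nets.eval()
        out = nets.forward_generator(batch)
        rec = out["recon"].data
        assert rec.shape == (2, 1, 32, 32)
        assert rec.min() >= 0.0 and rec.max() <= 1.0

    def test_segmentation_probabilities_sum_to_one(self, nets, batch):
        nets.eval()
        probs = nets.forward_generator(batch)["seg_probs"].data
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert set(np.unique(np.argmax(probs, axis=1))) <= {0, 1, 2, 3}

    def test_uniform_logits_give_quarter_probability(self):
        from cardisent.nn import softmax

        logits = Tensor(np.zeros((1, 4, 4, 4), dtype=np.float32))
        np.testing.assert_allclose(softmax(logits, axis=1).data, 0.25, atol=1e-7)

    def test_discriminator_scalar_per_sample_deterministic(self, nets):
        nets.eval()
        probs = Tensor(np.random.default_rng(0)
                       .dirichlet(np.ones(4), size=(2, 32, 32))
                       .transpose(0, 3, 1, 2).astype(np.float32))
        a = nets.di(probs).data
        assert a.shape == (2, 1)
        np.testing.assert_array_equal(a, nets.di(probs).data)


class TestEvoNormProjection:
    def test_eval_mode_deterministic_despite_dropout(self):
        rng = np.random.default_rng(0)
        layer = EvoNormProjection(4, 4, rng=rng, dropout=0.5)
        x = Tensor(rng.normal(size=(2, 4, 8, 8)).astype(np.float32))
        layer.train()
        layer(x)  # populate running stats
        layer.eval()
        np.testing.assert_array_equal(layer(x).data, layer(x).data)

    def test_zero_dropout_train_eval_agree_after_warmup(self):
        rng = np.random.default_rng(1)
        layer = EvoNormProjection(3, 3, rng=rng, dropout=0.0, momentum=1.0)
        x = Tensor(rng.normal(size=(4, 3, 8, 8)).astype(np.float32))
        layer.train()
        out_train = layer(x).data
        layer.eval()
        np.testing.assert_allclose(layer(x).data, out_train, atol=1e-5)

    def test_constant_input_finite(self):
        rng = np.random.default_rng(2)
        layer = EvoNormProjection(2, 2, rng=rng, dropout=0.0)
        x = Tensor(np.full((2, 2, 4, 4), 5.0, dtype=np.float32))
        layer.train()
        assert np.all(np.isfinite(layer(x).data))


def test_end_to_end_shape_contract_other_sizes():
    nets = DisentangleNets(CFG, seed=1)
    nets.eval()
    for size in (16, 48):
        x = Tensor(np.random.default_rng(0)
                   .uniform(0, 1, (1, 1, size, size)).astype(np.float32))
        out = nets.forward_generator(x)
        assert out["seg_probs"].shape == (1, 4, size, size)
        assert out["recon"].shape == (1, 1, size, size)
        assert out["factor"].hard.shape == (1, 8, size, size)


def test_gradient_reaches_every_generator_parameter():
    """One combined loss must touch all generator sub-networks."""
    nets = DisentangleNets(CFG, seed=2)
    nets.train()
    x = Tensor(np.random.default_rng(3)
               .uniform(0, 1, (2, 1, 16, 16)).astype(np.float32))
    y = np.eye(4, dtype=np.float32)[
        np.random.default_rng(4).integers(0, 4, (2, 16, 16))
    ].transpose(0, 3, 1, 2)
    out = nets.forward_generator(x)
    code = out["code"]
    loss = (
        L.weighted_soft_focal(y, out["seg_probs"])
        + L.sl2sim(x, out["recon"])
        + L.kl_gaussian(code.mu, code.logvar)
    )
    loss.backward()
    missing = [name for name, p in
               ((n, p) for mod in (nets.skeleton, nets.sentiency, nets.film,
                                   nets.spade, nets.recon, nets.seg)
                for n, p in mod.named_parameters())
               if p.grad is None or not np.any(p.grad)]
    assert missing == []
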