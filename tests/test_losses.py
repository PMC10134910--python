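"""Loss functions against independent brute-force oracles and closed forms.

Every pixel-wise loss is recomputed here by naive per-element summation on
tiny arrays (loops, float64) and must agree with the vectorized autodiff
implementation to 1e-6.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardisent import losses as L
from cardisent.networks import MineStatistic
from cardisent.nn import Tensor

# ------------------------------------------------------ brute-force oracles


def oracle_wsfl(y, p, a0, a1, gamma, w=None):
    y = np.asarray(y, dtype=np.float64).ravel()
    p = np.clip(np.asarray(p, dtype=np.float64).ravel(), 1e-7, 1 - 1e-7)
    w = np.ones_like(y) if w is None else np.asarray(w, dtype=np.float64).ravel()
    total = 0.0
    for yi, pi, wi in zip(y, p, w):
        alpha = a0 + yi * (a1 - a0)
        ce = -yi * np.log(pi) - (1 - yi) * np.log(1 - pi)
        total += alpha * abs(yi - pi) ** gamma * wi * ce
    return total / y.size


def oracle_bfd(y, p, gamma, eps):
    y = np.asarray(y, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    total = 0.0
    for c in range(y.shape[1]):
        yc, pc = y[:, c].ravel(), p[:, c].ravel()
        fg = (2 * np.sum(yc * pc) + eps) / (np.sum(yc) + np.sum(pc) + eps)
        bg = (2 * np.sum((1 - yc) * (1 - pc)) + eps) / (
            np.sum(1 - yc) + np.sum(1 - pc) + eps
        )
        total += max(2.0 - fg - bg, 0.0) ** (1.0 / gamma)
    return total


def oracle_ssim(x, y, window, sigma=1.5, k1=0.01, k2=0.03):
    half = window // 2
    u = np.arange(-half, half + 1, dtype=np.float64)
    g = np.exp(-(u**2) / (2 * sigma**2))
    kern = np.outer(g, g)
    kern /= kern.sum()
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    h, w = x.shape
    vals = []
    for i in range(h - window + 1):
        for j in range(w - window + 1):
            wx = x[i : i + window, j : j + window]
            wy = y[i : i + window, j : j + window]
            mx, my = (kern * wx).sum(), (kern * wy).sum()
            vx = (kern * wx * wx).sum() - mx**2
            vy = (kern * wy * wy).sum() - my**2
            cxy = (kern * wx * wy).sum() - mx * my
            c1, c2 = k1**2, k2**2
            vals.append(
                ((2 * mx * my + c1) * (2 * cxy + c2))
                / ((mx**2 + my**2 + c1) * (vx + vy + c2))
            )
    return float(np.mean(vals))


# --------------------------------------------------------------- WSFL / BFD
class TestWeightedSoftFocal:
    def test_matches_bruteforce_on_4x4_toys(self):
        rng = np.random.default_rng(0)
        y = (rng.random((2, 4, 4, 4)) > 0.5).astype(np.float32)
        p = rng.uniform(0.05, 0.95, size=y.shape).astype(np.float32)
        params = L.FocalParams(alpha0=0.25, alpha1=0.75, gamma=2.0, w_map="ones")
        got = L.weighted_soft_focal(y, p, params).item()
        assert got == pytest.approx(oracle_wsfl(y, p, 0.25, 0.75, 2.0), abs=1e-6)

    def test_gamma_zero_alpha_one_reduces_to_cross_entropy(self):
        # focal modulation off, uniform class weights: plain CE; at y=1,
        # p=0.5 that is -ln(0.5)
        y = np.ones((1, 1, 1, 1), dtype=np.float32)
        p = np.full_like(y, 0.5)
        with pytest.warns(UserWarning):
            params = L.FocalParams(alpha0=1.0, alpha1=1.0, gamma=0.0, w_map="ones")
        got = L.weighted_soft_focal(y, p, params).item()
        assert got == pytest.approx(-np.log(0.5), abs=1e-6)

    def test_perfect_prediction_vanishes(self):
        y = np.eye(4, dtype=np.float32)[
            np.random.default_rng(1).integers(0, 4, (2, 4, 4))
        ].transpose(0, 3, 1, 2)
        assert L.weighted_soft_focal(y, y).item() <= 1e-5

    def test_single_pixel_closed_form(self):
        # y=1, p=0.9, gamma=2, alpha=(0.25, 0.75):
        # 0.75 * 0.01 * (-ln 0.9) ~= 7.90e-4
        y = np.ones((1, 1, 1, 1), dtype=np.float32)
        p = np.full_like(y, 0.9)
        params = L.FocalParams(alpha0=0.25, alpha1=0.75, gamma=2.0, w_map="ones")
        expect = 0.75 * 0.01 * -np.log(0.9)
        assert L.weighted_soft_focal(y, p, params).item() == pytest.approx(
            expect, rel=1e-4
        )


class TestBackgroundFocalDice:
    def test_matches_bruteforce_on_2x2_toy(self):
        y = np.array([1, 1, 0, 0], dtype=np.float32).reshape(1, 1, 2, 2)
        p = np.array([0.8, 0.6, 0.3, 0.1], dtype=np.float32).reshape(1, 1, 2, 2)
        got = L.background_focal_dice(y, p, gamma=2.0, epsilon=1e-6).item()
        assert got == pytest.approx(oracle_bfd(y, p, 2.0, 1e-6), abs=1e-6)

    def test_matches_bruteforce_multiclass(self):
        rng = np.random.default_rng(3)
        y = np.eye(4, dtype=np.float32)[rng.integers(0, 4, (2, 4, 4))]
        y = y.transpose(0, 3, 1, 2)
        p = rng.uniform(0.01, 0.99, size=y.shape).astype(np.float32)
        got = L.background_focal_dice(y, p, gamma=1.5, epsilon=1e-6).item()
        assert got == pytest.approx(oracle_bfd(y, p, 1.5, 1e-6), abs=1e-6)

    def test_perfect_binary_prediction_is_zero(self):
        y = np.eye(4, dtype=np.float32)[
            np.random.default_rng(2).integers(0, 4, (1, 4, 4))
        ].transpose(0, 3, 1, 2)
        assert L.background_focal_dice(y, y).item() <= 1e-5

    def test_empty_class_guarded_by_epsilon(self):
        y = np.zeros((1, 1, 4, 4), dtype=np.float32)  # all background
        p = np.zeros_like(y)
        assert L.background_focal_dice(y, p).item() <= 1e-5


# -------------------------------------------------------------------- adv-GM
@pytest.mark.parametrize(
    "n,beta,expected",
    [(0.0, 0.5, 0.0), (1.0, 0.5, 0.5), (1e6, 0.5, None), (2.0, 1.0, 0.5)],
)
def test_adv_gm_saturating_form(n, beta, expected):
    val = L.adv_gm(np.float32(n), L.GMParams(beta=beta)).item()
    if expected is None:
        assert val >= 0.999
    else:
        assert val == pytest.approx(expected, abs=1e-6)


def test_adv_gm_rejects_beta_outside_unit_interval():
    with pytest.raises(ValueError):
        L.GMParams(beta=1.5)


# ------------------------------------------------------------------------ KL
class TestKLGaussian:
    def test_prior_equals_posterior_is_zero(self):
        z = np.zeros((3, 8), dtype=np.float32)
        assert L.kl_gaussian(z, z).item() == pytest.approx(0.0, abs=1e-7)

    def test_unit_mean_closed_form(self):
        mu = np.ones((1, 1), dtype=np.float32)
        lv = np.zeros((1, 1), dtype=np.float32)
        assert L.kl_gaussian(mu, lv).item() == pytest.approx(0.5, abs=1e-6)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        mu = rng.normal(0, 2, (2, 4)).astype(np.float32)
        lv = rng.normal(0, 1, (2, 4)).astype(np.float32)
        assert L.kl_gaussian(mu, lv).item() >= -1e-6


# -------------------------------------------------------------------- SL2SIM
class TestSL2SIM:
    def test_identical_images_zero(self):
        x = np.random.default_rng(0).uniform(0, 1, (12, 12)).astype(np.float32)
        assert L.sl2sim(x, x).item() == pytest.approx(0.0, abs=1e-5)

    def test_anticorrelated_exceeds_one(self):
        x = np.random.default_rng(1).uniform(0, 1, (16, 16)).astype(np.float32)
        assert L.sl2sim(x, 1.0 - x).item() > 1.0

    def test_matches_windowed_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, (4, 4)).astype(np.float32)
        y = rng.uniform(0, 1, (4, 4)).astype(np.float32)
        params = L.ReconParams(alpha_l2=1.0, ssim_window=3)
        expect = 1.0 - oracle_ssim(x, y, 3) + np.mean((x - y) ** 2)
        assert L.sl2sim(x, y, params).item() == pytest.approx(expect, abs=1e-6)

    def test_constant_images_l2_part(self):
        x = np.full((8, 8), 0.5, dtype=np.float32)
        y = np.full((8, 8), 0.25, dtype=np.float32)
        params = L.ReconParams(alpha_l2=1.0, ssim_window=7)
        expect = 1.0 - oracle_ssim(x, y, 7) + 0.0625
        assert L.sl2sim(x, y, params).item() == pytest.approx(expect, abs=1e-5)

    def test_agrees_with_skimage_gaussian_ssim(self):
        from skimage.metrics import structural_similarity

        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, (20, 20)).astype(np.float32)
        y = np.clip(x + rng.normal(0, 0.1, x.shape), 0, 1).astype(np.float32)
        ref = structural_similarity(
            x, y, win_size=7, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, data_range=1.0,
        )
        got = L.ssim(x, y, L.ReconParams(ssim_window=7)).item()
        assert got == pytest.approx(ref, abs=2e-3)


# ---------------------------------------------------------------------- MINE
class TestMine:
    def test_constant_statistic_gives_zero(self):
        rng = np.random.default_rng(0)
        net = MineStatistic(rng=rng, in_dim=2)
        for p in net.parameters():
            p.data[:] = 0.0
        net.l3.bias.data[:] = 3.7  # T == 3.7 everywhere
        joint = Tensor(rng.normal(size=(16, 2)).astype(np.float32))
        marg = Tensor(rng.normal(size=(16, 2)).astype(np.float32))
        assert L.mine_estimate(net, joint, marg).item() == pytest.approx(0.0, abs=1e-5)

    def test_requires_two_samples(self):
        rng = np.random.default_rng(0)
        net = MineStatistic(rng=rng, in_dim=2)
        one = Tensor(np.zeros((1, 2), dtype=np.float32))
        with pytest.raises(ValueError):
            L.mine_estimate(net, one, one)


# --------------------------------------------------------------------- total
class TestTotalLoss:
    def test_all_zero(self):
        comps = {k: 0.0 for k in L._COMPONENT_KEYS}
        assert L.total_loss(comps).item() == 0.0

    def test_unit_components_with_default_weights(self):
        comps = {k: 1.0 for k in L._COMPONENT_KEYS}
        # 10*1 + 10*(1+1) + 0.01*1 + 0.01*(1+1) + 1*1 = 31.03
        assert L.total_loss(comps).item() == pytest.approx(31.03, abs=1e-4)

    def test_paper_style_weighting_sums(self):
        comps = dict(seg_sup=1.0, adv_lab=1.0, adv_unlab=0.0, vae=1.0,
                     rec_lab=1.0, rec_unlab=0.0, mim=1.0)
        # 10 + 10 + 0.01 + 0.01 + 1 = 21.02
        assert L.total_loss(comps).item() == pytest.approx(21.02, abs=1e-4)

    def test_doubling_lambda_seg_doubles_that_term_only(self):
        comps = dict(seg_sup=2.0, adv_lab=0.5, adv_unlab=0.5, vae=1.0,
                     rec_lab=0.3, rec_unlab=0.3, mim=0.2)
        w1 = L.LossWeights()
        w2 = L.LossWeights(lambda_seg=2 * w1.lambda_seg)
        diff = L.total_loss(comps, w2).item() - L.total_loss(comps, w1).item()
        assert diff == pytest.approx(w1.lambda_seg * comps["seg_sup"], abs=1e-5)

    def test_negative_kl_rejected(self):
        comps = {k: 0.0 for k in L._COMPONENT_KEYS}
        comps["vae"] = -0.5
        with pytest.raises(ValueError):
            L.total_loss(comps)

    def test_missing_component_rejected(self):
        with pytest.raises(ValueError):
            L.total_loss({"seg_sup": 1.0})


# ---------------------------------------------------------------- properties
@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_losses_finite_and_nonnegative_on_clamped_inputs(seed):
    rng = np.random.default_rng(seed)
    y = np.eye(4, dtype=np.float32)[rng.integers(0, 4, (1, 4, 4))]
    y = y.transpose(0, 3, 1, 2)
    p = rng.uniform(0, 1, size=y.shape).astype(np.float32)
    p /= p.sum(axis=1, keepdims=True)
    for value in (
        L.weighted_soft_focal(y, p).item(),
        L.background_focal_dice(y, p).item(),
        L.adv_gm(np.float32(rng.uniform(0, 100))).item(),
    ):
        assert np.isfinite(value) and value >= 0
    assert L.adv_gm(np.float32(rng.uniform(0, 1e5))).item() < 1.0
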