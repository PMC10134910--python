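"""Training objectives: focal segmentation losses, robust adversarial loss,
VAE KL, SSIM+L2 reconstruction loss, and the MINE mutual-information bound.

All functions accept either numpy arrays or autodiff tensors and return a
scalar :class:`~cardisent.nn.Tensor`, so the same code path is exercised by
the brute-force oracle tests and by training.

Conventions
-----------
* probabilities are clamped to [1e-7, 1 - 1e-7] before any logarithm;
* every expectation reduces with the mean over the batch;
* the Geman-McClure adversarial saturation is N / (2*beta + N), applied to
  a least-squares GAN residual N >= 0, so its value always lies in [0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, as_tensor, conv2d, log_clamped

_EPS_PROB = 1e-7


# ----------------------------------------------------------------- parameters
@dataclass
class FocalParams:
    alpha0: float = 0.25  # background class weight
    alpha1: float = 0.75  # foreground class weight
    gamma: float = 2.0  # focusing exponent, conventionally in [1, 3]
    epsilon: float = 1e-6  # dice smoothing
    w_map: str = "inverse_freq"  # "ones" | "inverse_freq" | explicit array

    def __post_init__(self):
        if not 1.0 <= self.gamma <= 3.0:
            import warnings

            warnings.warn(f"focusing exponent gamma={self.gamma} outside [1, 3]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass
class GMParams:
    beta: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")


@dataclass
class LossWeights:
    lambda_vae: float = 0.01
    lambda_seg: float = 10.0
    lambda_adv_gm: float = 10.0
    lambda_sl2sim: float = 0.01
    lambda_mim: float = 1.0

    def __post_init__(self):
        for name, value in vars(self).items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ReconParams:
    alpha_l2: float = 1.0
    ssim_window: int = 7
    ssim_k1: float = 0.01
    ssim_k2: float = 0.03

    def __post_init__(self):
        if self.alpha_l2 < 0:
            raise ValueError("alpha_l2 must be >= 0")
        if self.ssim_window % 2 == 0:
            raise ValueError("ssim_window must be odd")


# -------------------------------------------------------------------- helpers
def _clamp_prob(p: Tensor) -> Tensor:
    return as_tensor(p).clip(_EPS_PROB, 1.0 - _EPS_PROB)


def _weight_map(y: np.ndarray, spec) -> np.ndarray:
    """Per-class inverse-frequency weights within the batch, mean 1."""
    if isinstance(spec, np.ndarray):
        return spec.astype(np.float32)
    if spec in (None, "ones", 1):
        return np.ones_like(y, dtype=np.float32)
    if spec != "inverse_freq":
        raise ValueError(f"unknown w_map spec: {spec!r}")
    axes = tuple(i for i in range(y.ndim) if i != 1)  # all but the class axis
    freq = y.mean(axis=axes, keepdims=True)
    inv = 1.0 / np.maximum(freq, 1e-3)  # floor keeps absent classes bounded
    w = np.broadcast_to(inv, y.shape).astype(np.float32)
    return (w / w.mean()).astype(np.float32)


def binary_cross_entropy(y: Tensor, p: Tensor) -> Tensor:
    p = _clamp_prob(p)
    y = as_tensor(y)
    return -(y * p.log() + (1.0 - y) * (1.0 - p).log())


# ------------------------------------------------------------------ WSFL/BFD
def weighted_soft_focal(y_onehot, y_prob, params: FocalParams | None = None) -> Tensor:
    """Weighted soft focal loss.

    Mean over pixels and classes of
    ``(alpha0 + y*(alpha1 - alpha0)) * |y - p|^gamma * w * CE(y, p)``,
    where CE is the per-element binary cross-entropy.  The focal modulation
    down-weighs easy (well-classified) pixels; the alpha pair and the weight
    map address foreground/background imbalance.
    """
    params = params or FocalParams()
    y = as_tensor(y_onehot)
    p = _clamp_prob(y_prob)
    w = Tensor(_weight_map(y.data, params.w_map))
    alpha = params.alpha0 + y * (params.alpha1 - params.alpha0)
    focal = (y - p).abs() ** params.gamma
    ce = binary_cross_entropy(y, p)
    return (alpha * focal * w * ce).mean()


def _soft_dice(a: Tensor, b: Tensor, axes, eps: float) -> Tensor:
    num = 2.0 * (a * b).sum(axis=axes) + eps
    den = (a + b).sum(axis=axes) + eps
    return num / den


def background_focal_dice(y_onehot, y_prob, gamma: float = 2.0,
                          epsilon: float = 1e-6) -> Tensor:
    """Background focal dice loss.

    Per class c:  ``[2 - dice(y_c, p_c) - dice(1-y_c, 1-p_c)]^(1/gamma)``,
    summed over classes.  The complement term scores the background of each
    class, so empty structures are still graded; the epsilon smoothing keeps
    empty-vs-empty comparisons at dice 1.
    """
    y = as_tensor(y_onehot)
    p = as_tensor(y_prob)
    if y.ndim != 4:
        raise ValueError("expected (B, L, H, W) inputs")
    axes = (0, 2, 3)  # reduce over batch and pixels, keep classes
    fg = _soft_dice(y, p, axes, epsilon)
    bg = _soft_dice(1.0 - y, 1.0 - p, axes, epsilon)
    base = (2.0 - fg - bg).maximum(Tensor(np.zeros(fg.shape, dtype=np.float32)))
    return ((base + 1e-12) ** (1.0 / gamma)).sum()


def soft_dice_ce(y_onehot, y_prob, epsilon: float = 1e-6) -> Tensor:
    """Plain Dice + categorical cross-entropy (ablation baseline loss)."""
    y = as_tensor(y_onehot)
    p = _clamp_prob(y_prob)
    dice = _soft_dice(y, p, (0, 2, 3), epsilon)
    ce = -(y * p.log()).sum(axis=1).mean()
    return (1.0 - dice.mean()) + ce


# --------------------------------------------------------------------- adv-GM
def adv_gm(residual_sum, params: GMParams | None = None) -> Tensor:
    """Geman-McClure saturation of a least-squares adversarial residual."""
    params = params or GMParams()
    n = as_tensor(residual_sum)
    return n / (2.0 * params.beta + n)


def lsgan_discriminator_residual(d_fake: Tensor, d_real: Tensor) -> Tensor:
    """E[D(fake)^2] + E[(D(real) - 1)^2] (discriminator step)."""
    return (as_tensor(d_fake) ** 2).mean() + ((as_tensor(d_real) - 1.0) ** 2).mean()


def lsgan_generator_residual(d_fake: Tensor) -> Tensor:
    """E[(D(fake) - 1)^2] (generator step)."""
    return ((as_tensor(d_fake) - 1.0) ** 2).mean()


# ------------------------------------------------------------------------ KL
def kl_gaussian(mu, logvar) -> Tensor:
    """KL(N(mu, sigma^2) || N(0, I)), mean over the batch."""
    mu = as_tensor(mu)
    logvar = as_tensor(logvar)
    per_sample = 0.5 * (mu**2 + logvar.exp() - 1.0 - logvar).sum(axis=1)
    return per_sample.mean()


# --------------------------------------------------------------------- SL2SIM
def _gaussian_kernel(window: int, sigma: float = 1.5) -> np.ndarray:
    half = window // 2
    x = np.arange(-half, half + 1, dtype=np.float64)
    g = np.exp(-(x**2) / (2 * sigma**2))
    k = np.outer(g, g)
    return (k / k.sum()).astype(np.float32)


def ssim(x, x_hat, params: ReconParams | None = None) -> Tensor:
    """Windowed structural similarity with a Gaussian window, data range 1."""
    params = params or ReconParams()
    x = as_tensor(x)
    y = as_tensor(x_hat)
    if x.ndim == 2:
        x = x.reshape(1, 1, *x.shape)
        y = y.reshape(1, 1, *y.shape)
    elif x.ndim == 3:
        x = x.reshape(x.shape[0], 1, *x.shape[1:])
        y = y.reshape(y.shape[0], 1, *y.shape[1:])
    if params.ssim_window > min(x.shape[-2:]):
        raise ValueError("ssim_window larger than the image")
    k = Tensor(_gaussian_kernel(params.ssim_window)[None, None])
    c1 = (params.ssim_k1) ** 2
    c2 = (params.ssim_k2) ** 2

    def filt(t):
        return conv2d(t, k, padding=0)

    mu_x, mu_y = filt(x), filt(y)
    sig_x = filt(x * x) - mu_x * mu_x
    sig_y = filt(y * y) - mu_y * mu_y
    cov = filt(x * y) - mu_x * mu_y
    num = (2.0 * mu_x * mu_y + c1) * (2.0 * cov + c2)
    den = (mu_x * mu_x + mu_y * mu_y + c1) * (sig_x + sig_y + c2)
    return (num / den).mean()


def sl2sim(x, x_hat, params: ReconParams | None = None) -> Tensor:
    """1 - SSIM(x, x_hat) + alpha_l2 * mean((x - x_hat)^2)."""
    params = params or ReconParams()
    x_t, y_t = as_tensor(x), as_tensor(x_hat)
    l2 = ((x_t - y_t) ** 2).mean()
    return (1.0 - ssim(x_t, y_t, params)) + params.alpha_l2 * l2


# ----------------------------------------------------------------------- MINE
def mine_estimate(stat_net, joint_pairs, marginal_pairs) -> Tensor:
    """Donsker-Varadhan lower bound on mutual information.

    ``joint_pairs`` are aligned (summary, code) rows; ``marginal_pairs`` are
    the same rows with the second component permuted within the batch.  The
    log argument is clamped below at 1e-8 for numerical safety.
    """
    joint_pairs = as_tensor(joint_pairs)
    marginal_pairs = as_tensor(marginal_pairs)
    if joint_pairs.shape[0] < 2:
        raise ValueError("MINE needs at least two samples")
    t_joint = stat_net(joint_pairs)
    t_marg = stat_net(marginal_pairs)
    return t_joint.mean() - log_clamped(t_marg.exp().mean(), 1e-8)


# ---------------------------------------------------------------------- total
_COMPONENT_KEYS = ("seg_sup", "adv_lab", "adv_unlab", "vae", "rec_lab",
                   "rec_unlab", "mim")


def total_loss(components: dict, weights: LossWeights | None = None) -> Tensor:
    """Weighted sum of all objective components.

    ``components`` must contain every key in ``{seg_sup, adv_lab, adv_unlab,
    vae, rec_lab, rec_unlab, mim}`` (scalars or tensors; unlabeled-only
    terms may be zero).  The KL and supervised segmentation terms are
    contractually non-negative and are validated.
    """
    weights = weights or LossWeights()
    missing = [k for k in _COMPONENT_KEYS if k not in components]
    if missing:
        raise ValueError(f"missing loss components: {missing}")
    c = {k: as_tensor(v) for k, v in components.items()}
    for key in ("seg_sup", "vae"):
        if float(c[key].data) < -1e-6:
            raise ValueError(f"component {key} must be non-negative")
    return (
        weights.lambda_seg * c["seg_sup"]
        + weights.lambda_adv_gm * (c["adv_lab"] + c["adv_unlab"])
        + weights.lambda_vae * c["vae"]
        + weights.lambda_sl2sim * (c["rec_lab"] + c["rec_unlab"])
        + weights.lambda_mim * c["mim"]
    )
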