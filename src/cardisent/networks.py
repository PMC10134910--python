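"""Model components: spatial-factor encoder, style VAE encoder, FiLM and
SPADE conditioned decoders, fusion reconstructor, segmentor, discriminators
and the MINE statistic network.

The design separates an image into

* a *spatial factor* ``f_SK``: an 8-channel near-binary map of the anatomy,
  produced by a nested-skip (U-Net++ style) encoder whose skip connections
  are normalized 1x1 projections, with eight lightweight decoders attached
  at the bottleneck, each emitting one sigmoid channel that is binarized by
  straight-through rounding (hard forward value, soft gradient); and
* a *sentiency code* ``z``: a low-dimensional VAE latent capturing scanner
  appearance (intensity, contrast), sampled with the reparameterization
  trick at training time and set to the posterior mean at evaluation.

Reconstruction re-entangles the two factors through a FiLM-conditioned
convolution stack and a SPADE (shape-aware denormalization) decoder whose
outputs are fused by a 1x1 convolution.  Segmentation consumes the spatial
factor alone by default, which makes the predicted mask independent of the
style code by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    ConvBlock,
    EvoNormProjection,
    Linear,
    Module,
    Tensor,
    avg_pool2d,
    concat,
    softmax,
    upsample_nearest2d,
)

N_FACTOR_CHANNELS = 8
N_CLASSES = 4


@dataclass
class NetConfig:
    base_filters: int = 16
    depth: int = 2  # number of downsamplings in the spatial encoder
    latent_dim: int = 8
    dropout: float = 0.1
    seg_width: int = 64
    disc_filters: int = 16
    si_input: str = "skeleton"  # "skeleton" | "film"
    binarize: bool = True  # False: no disentangler (continuous features)
    init: str = "he_normal"

    def __post_init__(self):
        if self.base_filters < 4:
            raise ValueError("base_filters must be >= 4")
        if self.si_input not in ("skeleton", "film"):
            raise ValueError("si_input must be 'skeleton' or 'film'")


@dataclass
class SpatialFactor:
    """Domain-invariant 8-channel map; ``hard`` = 1[soft > 0.5]."""

    soft: Tensor  # (B, 8, H, W) in [0, 1]
    hard: Tensor  # (B, 8, H, W) in {0, 1}, straight-through gradient


@dataclass
class SentiencyCode:
    """VAE posterior (mu, logvar) and the sample z = mu + sigma * eps."""

    mu: Tensor
    logvar: Tensor
    z: Tensor
    eps: np.ndarray = field(repr=False, default=None)


# ----------------------------------------------------------- spatial encoder
class SkeletonEncoder(Module):
    """Nested-skip encoder with eight per-channel decoders at the bottleneck.

    Topology (depth 2): backbone nodes X00 -> X10 -> X20 with average-pool
    downsampling; nested nodes X01, X11, X02 merge upsampled deeper features
    with normalized-projection skips; eight small decoders rise from the
    bottleneck, merging the nested features at each resolution, and emit one
    sigmoid channel each.
    """

    def __init__(self, cfg: NetConfig, *, rng):
        super().__init__()
        if cfg.depth != 2:
            raise ValueError("the spatial encoder is built for depth 2")
        f = cfg.base_filters
        d = cfg.dropout
        self.cfg = cfg
        self.x00 = ConvBlock(1, f, rng=rng)
        self.x10 = ConvBlock(f, 2 * f, rng=rng)
        self.x20 = ConvBlock(2 * f, 4 * f, rng=rng)
        self.p00 = EvoNormProjection(f, f, rng=rng, dropout=d)
        self.p10 = EvoNormProjection(2 * f, 2 * f, rng=rng, dropout=d)
        self.p01 = EvoNormProjection(f, f, rng=rng, dropout=d)
        self.x01 = ConvBlock(3 * f, f, rng=rng)
        self.x11 = ConvBlock(6 * f, 2 * f, rng=rng)
        self.x02 = ConvBlock(4 * f, f, rng=rng)
        w = N_FACTOR_CHANNELS
        self.dec_up1 = [Conv2d(4 * f + 2 * f, w, rng=rng) for _ in range(w)]
        self.dec_up0 = [Conv2d(w + f, w, rng=rng) for _ in range(w)]
        self.dec_out = [Conv2d(w, 1, k=1, rng=rng) for _ in range(w)]

    def forward(self, image: Tensor) -> SpatialFactor:
        h = image.shape[-1]
        if h % (2**self.cfg.depth) or image.shape[-2] % (2**self.cfg.depth):
            raise ValueError(
                f"image size {image.shape[-2:]} not divisible by 2^depth"
            )
        x00 = self.x00(image)
        x10 = self.x10(avg_pool2d(x00))
        x20 = self.x20(avg_pool2d(x10))
        x01 = self.x01(concat([self.p00(x00), upsample_nearest2d(x10)], axis=1))
        x11 = self.x11(concat([self.p10(x10), upsample_nearest2d(x20)], axis=1))
        x02 = self.x02(
            concat([self.p00(x00), self.p01(x01), upsample_nearest2d(x11)], axis=1)
        )
        channels = []
        up20 = upsample_nearest2d(x20)
        for c1, c0, out in zip(self.dec_up1, self.dec_up0, self.dec_out):
            h1 = c1(concat([up20, x11], axis=1)).leaky_relu(0.2)
            h0 = c0(concat([upsample_nearest2d(h1), x02], axis=1)).leaky_relu(0.2)
            channels.append(out(h0).sigmoid())
        soft = concat(channels, axis=1)
        hard = soft.round_ste(0.5) if self.cfg.binarize else soft
        return SpatialFactor(soft=soft, hard=hard)


def skeleton_encode(encoder: SkeletonEncoder, image) -> SpatialFactor:
    return encoder(image if isinstance(image, Tensor) else Tensor(image))


# ---------------------------------------------------------- sentiency encoder
class SentiencyEncoder(Module):
    """Convolutional VAE encoder over (image, spatial factor) pairs.

    Deliberately free of normalization layers: batch/instance statistics
    would strip exactly the global intensity and contrast information the
    style code is meant to capture.
    """

    def __init__(self, cfg: NetConfig, *, rng):
        super().__init__()
        f = cfg.base_filters
        self.latent_dim = cfg.latent_dim
        self.rng = rng
        self.c1 = Conv2d(1 + N_FACTOR_CHANNELS, f, stride=2, padding=1, rng=rng)
        self.c2 = Conv2d(f, 2 * f, stride=2, padding=1, rng=rng)
        self.c3 = Conv2d(2 * f, 4 * f, stride=2, padding=1, rng=rng)
        self.fc_mu = Linear(4 * f, cfg.latent_dim, rng=rng)
        self.fc_logvar = Linear(4 * f, cfg.latent_dim, rng=rng)
        # start with a narrow posterior (sigma ~ exp(-1)) so the code is not
        # drowned in reparameterization noise before the decoders learn to
        # read it; the KL term pulls sigma back toward 1
        self.fc_logvar.bias.data[:] = -2.0

    def forward(self, image: Tensor, factor: SpatialFactor,
                eps: np.ndarray | None = None) -> SentiencyCode:
        h = concat([image, factor.soft], axis=1)
        h = self.c1(h).leaky_relu(0.2)
        h = self.c2(h).leaky_relu(0.2)
        h = self.c3(h).leaky_relu(0.2)
        pooled = h.mean(axis=(2, 3))
        mu = self.fc_mu(pooled)
        logvar = self.fc_logvar(pooled)
        if not self.training:
            eps = np.zeros(mu.shape, dtype=np.float32)
        elif eps is None:
            eps = self.rng.standard_normal(mu.shape).astype(np.float32)
        z = mu + (logvar * 0.5).exp() * Tensor(eps)
        return SentiencyCode(mu=mu, logvar=logvar, z=z, eps=eps)


def sentiency_encode(encoder: SentiencyEncoder, image, factor,
                     eps=None) -> SentiencyCode:
    return encoder(image if isinstance(image, Tensor) else Tensor(image),
                   factor, eps)


# ------------------------------------------------------------------- FiLM
def film_modulate(feature: Tensor, gamma: Tensor, beta: Tensor) -> Tensor:
    """Per-channel affine modulation gamma * F + beta."""
    feature = feature if isinstance(feature, Tensor) else Tensor(feature)
    gamma = gamma if isinstance(gamma, Tensor) else Tensor(gamma)
    beta = beta if isinstance(beta, Tensor) else Tensor(beta)
    c = feature.shape[1]
    if gamma.ndim == 2:
        if gamma.shape[1] != c:
            raise ValueError("gamma/beta channel count mismatch")
        gamma = gamma.reshape(gamma.shape[0], c, 1, 1)
        beta = beta.reshape(beta.shape[0], c, 1, 1)
    elif gamma.shape[-3] != c and gamma.data.size != 1:
        raise ValueError("gamma/beta not broadcastable per channel")
    return gamma * feature + beta


class FilmDecoder(Module):
    """Conv stack (8, 8, 8, 8, 1 channels, 3x3, stride 1) with per-layer
    FiLM conditioning predicted from z; batch-norm + leaky-ReLU between
    layers.  Returns the final 1-channel map (to the reconstructor) and the
    penultimate 8-channel features.
    """

    CHANNELS = (8, 8, 8, 8)

    def __init__(self, cfg: NetConfig, *, rng):
        super().__init__()
        chans = self.CHANNELS
        self.convs = []
        self.norms = []
        cin = N_FACTOR_CHANNELS
        for c in chans:
            self.convs.append(Conv2d(cin, c, rng=rng))
            self.norms.append(BatchNorm2d(c))
            cin = c
        self.final = Conv2d(cin, 1, rng=rng)
        n_mod = 2 * sum(chans)
        self.pred_hidden = Linear(cfg.latent_dim, 64, rng=rng)
        # zero-init offsets: conditioning starts at the identity (1, 0)
        self.pred_out = Linear(64, n_mod, rng=rng, zero_init=True)

    def predict_gamma_beta(self, z: Tensor):
        h = self.pred_hidden(z).leaky_relu(0.2)
        out = self.pred_out(h)
        gammas, betas = [], []
        ofs = 0
        for c in self.CHANNELS:
            gammas.append(1.0 + out[:, ofs : ofs + c])
            betas.append(out[:, ofs + c : ofs + 2 * c])
            ofs += 2 * c
        return gammas, betas

    def forward(self, factor: SpatialFactor, code: SentiencyCode):
        gammas, betas = self.predict_gamma_beta(code.z)
        h = factor.hard
        for conv, norm, g, b in zip(self.convs, self.norms, gammas, betas):
            h = film_modulate(norm(conv(h)), g, b).leaky_relu(0.2)
        return self.final(h), h  # (reconstruction features, segmentor input)


def film_decode(decoder: FilmDecoder, factor, code):
    return decoder(factor, code)


# ------------------------------------------------------------------- SPADE
class SpadeNorm(Module):
    """Shape-aware normalization.

    The input feature is instance-normalized (its mean/scale optionally
    re-modulated by a shift/scale learned from z, zero-initialized so the
    modulation starts at the identity) and then denormalized spatially:
    ``F_out = F_norm * gamma(f_SK) + beta(f_SK)``, where gamma and beta come
    from three convolutions on the (nearest-neighbour interpolated) hard
    spatial factor — one shared encoding layer and two heads.
    """

    def __init__(self, channels: int, cfg: NetConfig, *, rng, hidden: int = 16):
        super().__init__()
        self.eps = 1e-5
        self.shared = Conv2d(N_FACTOR_CHANNELS, hidden, rng=rng)
        self.head_gamma = Conv2d(hidden, channels, rng=rng)
        self.head_beta = Conv2d(hidden, channels, rng=rng)
        self.z_mod = Linear(cfg.latent_dim, 2 * channels, rng=rng, zero_init=True)
        self.channels = channels

    @staticmethod
    def _match_size(fsk: Tensor, target_hw: tuple[int, int]) -> Tensor:
        h, w = fsk.shape[-2:]
        th, tw = target_hw
        if (h, w) == (th, tw):
            return fsk
        if th % h == 0 and tw % w == 0 and th // h == tw // w:
            return upsample_nearest2d(fsk, th // h)
        if h % th == 0 and w % tw == 0 and h // th == w // tw:
            s = h // th
            return fsk[:, :, s // 2 :: s, s // 2 :: s]
        raise ValueError("spatial factor size incommensurate with feature size")

    def forward(self, f_in: Tensor, factor: SpatialFactor, z: Tensor) -> Tensor:
        mu = f_in.mean(axis=(2, 3), keepdims=True)
        var = ((f_in - mu) ** 2).mean(axis=(2, 3), keepdims=True)
        x = (f_in - mu) / ((var + self.eps) ** 0.5)
        mod = self.z_mod(z)
        b = mod.shape[0]
        s = mod[:, : self.channels].reshape(b, self.channels, 1, 1)
        t = mod[:, self.channels :].reshape(b, self.channels, 1, 1)
        x = x * (1.0 + s) + t
        fsk = self._match_size(factor.hard, f_in.shape[-2:])
        shared = self.shared(fsk).relu()
        gamma = self.head_gamma(shared)
        beta = self.head_beta(shared)
        return x * gamma + beta


def spade_normalize(norm: SpadeNorm, f_in, factor, z) -> Tensor:
    return norm(f_in if isinstance(f_in, Tensor) else Tensor(f_in), factor, z)


class SpadeDecoder(Module):
    """Maps z to an image-sized feature map through SPADE + convolution
    blocks conditioned on the spatial factor.

    z is projected to a coarse spatial map (not a per-channel constant: the
    first instance normalization would annihilate a constant field and with
    it all style information) and upsampled to the image grid.
    """

    BASE = 4  # side of the coarse z-projection grid

    def __init__(self, cfg: NetConfig, *, rng, width: int = 8, n_blocks: int = 2):
        super().__init__()
        self.width = width
        self.embed = Linear(cfg.latent_dim, width * self.BASE * self.BASE, rng=rng)
        self.norms = [SpadeNorm(width, cfg, rng=rng) for _ in range(n_blocks)]
        self.convs = [Conv2d(width, width, rng=rng) for _ in range(n_blocks)]

    def forward(self, code: SentiencyCode, factor: SpatialFactor) -> Tensor:
        b = code.z.shape[0]
        h, w = factor.hard.shape[-2:]
        if h % self.BASE or w % self.BASE or h // self.BASE != w // self.BASE:
            raise ValueError("image size must be a square multiple of 4")
        x = self.embed(code.z).reshape(b, self.width, self.BASE, self.BASE)
        x = upsample_nearest2d(x, h // self.BASE)
        for norm, conv in zip(self.norms, self.convs):
            x = conv(norm(x, factor, code.z).leaky_relu(0.2))
        return x


def spade_decode(decoder: SpadeDecoder, code, factor) -> Tensor:
    return decoder(code, factor)


# -------------------------------------------------------------- reconstructor
class Reconstructor(Module):
    """Re-entangles the two decoder outputs: channel concatenation followed
    by a 1x1 fusion convolution and a sigmoid to [0, 1]."""

    def __init__(self, cfg: NetConfig, *, rng, spade_width: int = 8):
        super().__init__()
        self.fuse = Conv2d(1 + spade_width, 1, k=1, rng=rng)

    def forward(self, film_features: Tensor, spade_features: Tensor) -> Tensor:
        if film_features.shape[-2:] != spade_features.shape[-2:]:
            raise ValueError("decoder outputs must share a spatial size")
        return self.fuse(concat([film_features, spade_features], axis=1)).sigmoid()


def reconstruct(recon: Reconstructor, film_features, spade_features) -> Tensor:
    return recon(film_features, spade_features)


# ------------------------------------------------------------------ segmentor
class Segmentor(Module):
    """Three 3x3 convolutions (w, w, L channels) with softmax over L=4."""

    def __init__(self, cfg: NetConfig, *, rng):
        super().__init__()
        w = cfg.seg_width
        cin = N_FACTOR_CHANNELS
        self.c1 = Conv2d(cin, w, rng=rng)
        self.b1 = BatchNorm2d(w)
        self.c2 = Conv2d(w, w, rng=rng)
        self.b2 = BatchNorm2d(w)
        self.c3 = Conv2d(w, N_CLASSES, rng=rng)

    def forward(self, features: Tensor) -> Tensor:
        h = self.b1(self.c1(features)).leaky_relu(0.2)
        h = self.b2(self.c2(h)).leaky_relu(0.2)
        return softmax(self.c3(h), axis=1)


def segment(segmentor: Segmentor, features) -> Tensor:
    return segmentor(features if isinstance(features, Tensor) else Tensor(features))


# -------------------------------------------------------------- discriminator
class Discriminator(Module):
    """DCGAN-style strided stack over mask probabilities; least-squares
    head: one unbounded scalar per sample, no sigmoid."""

    def __init__(self, cfg: NetConfig, *, rng):
        super().__init__()
        f = cfg.disc_filters
        self.c1 = Conv2d(N_CLASSES, f, stride=2, padding=1, rng=rng)
        self.c2 = Conv2d(f, 2 * f, stride=2, padding=1, rng=rng)
        self.c3 = Conv2d(2 * f, 4 * f, stride=2, padding=1, rng=rng)
        self.fc = Linear(4 * f, 1, rng=rng)

    def forward(self, probs: Tensor) -> Tensor:
        h = self.c1(probs).leaky_relu(0.2)
        h = self.c2(h).leaky_relu(0.2)
        h = self.c3(h).leaky_relu(0.2)
        return self.fc(h.mean(axis=(2, 3)))


def discriminate(disc: Discriminator, probs) -> Tensor:
    return disc(probs if isinstance(probs, Tensor) else Tensor(probs))


# ----------------------------------------------------------------------- MINE
class MineStatistic(Module):
    """3-layer perceptron statistic T on (pooled f_SK, z) pairs."""

    def __init__(self, cfg: NetConfig | None = None, *, rng, hidden: int = 64,
                 in_dim: int | None = None):
        super().__init__()
        if in_dim is None:
            in_dim = N_FACTOR_CHANNELS + (cfg.latent_dim if cfg else 8)
        fin = in_dim
        self.l1 = Linear(fin, hidden, rng=rng)
        self.l2 = Linear(hidden, hidden, rng=rng)
        self.l3 = Linear(hidden, 1, rng=rng)

    def forward(self, pairs: Tensor) -> Tensor:
        h = self.l1(pairs).relu()
        h = self.l2(h).relu()
        return self.l3(h)


# --------------------------------------------------------------------- bundle
class DisentangleNets(Module):
    """All sub-networks of the semi-supervised segmentation model."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        self.cfg = cfg
        self.skeleton = SkeletonEncoder(cfg, rng=rng)
        self.sentiency = SentiencyEncoder(cfg, rng=rng)
        self.film = FilmDecoder(cfg, rng=rng)
        self.spade = SpadeDecoder(cfg, rng=rng)
        self.recon = Reconstructor(cfg, rng=rng)
        self.seg = Segmentor(cfg, rng=rng)
        self.di = Discriminator(cfg, rng=rng)
        self.diu = Discriminator(cfg, rng=rng)
        self.mine = MineStatistic(cfg, rng=rng)

    # parameter groups ------------------------------------------------------
    def generator_parameters(self):
        out = []
        for mod in (self.skeleton, self.sentiency, self.film, self.spade,
                    self.recon, self.seg):
            out.extend(mod.parameters())
        return out

    def segmentor_input(self, factor: SpatialFactor, film_penult: Tensor | None):
        if self.cfg.si_input == "skeleton":
            return factor.hard
        if film_penult is None:
            raise ValueError("si_input='film' requires the FiLM features")
        return film_penult

    def forward_generator(self, image: Tensor, with_reconstruction: bool = True,
                          eps: np.ndarray | None = None) -> dict:
        factor = self.skeleton(image)
        out = {"factor": factor}
        if with_reconstruction or self.cfg.si_input == "film":
            code = self.sentiency(image, factor, eps=eps)
            film_out, film_penult = self.film(factor, code)
            out.update(code=code, film_out=film_out, film_penult=film_penult)
        else:
            code, film_penult = None, None
        out["seg_probs"] = self.seg(self.segmentor_input(factor, film_penult))
        if with_reconstruction:
            spade_feats = self.spade(code, factor)
            out["recon"] = self.recon(out["film_out"], spade_feats)
        return out

    def pooled_factor(self, factor: SpatialFactor) -> Tensor:
        return factor.soft.mean(axis=(2, 3))
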