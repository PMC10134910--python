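"""Semi-supervised optimization loop and ablation variants.

Each step performs, in order: (1) discriminator updates (one per stream)
minimizing their adversarial losses against labeled ground-truth one-hot
masks, (2) a MINE statistic-network update maximizing the mutual-information
bound, and (3) a main update of both encoders, both decoders, the
reconstructor and the segmentor minimizing the weighted total objective with
the variant's active terms.  Discriminator and generator parameters never
share an optimizer step; disabled terms enter the total as exact zeros, so
they contribute no gradient.

Variants
--------
``full``        all terms (GAN + reconstruction + disentanglement + MIM)
``no_wsfl``     drop the weighted soft focal term, keep the focal dice term
``no_advgm``    plain least-squares adversarial loss (no robust saturation)
``dice_ce``     plain Dice + cross-entropy supervision
``no_mim``      drop mutual-information minimization
``model1``      GAN path only (supervision + adversarial)
``model2``      GAN + reconstruction (no MIM)
``supervised``  supervised segmentation loss only
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import losses as L
from . import pipeline
from .evaluation import dice
from .networks import DisentangleNets, NetConfig
from .nn import Adam, Tensor, clip_grad_norm, concat
from .phantom import PhantomStudy, augment

VARIANT_ALIASES = {
    "full": "full", "model-iii": "full", "model3": "full", "cqsl": "full",
    "1cqsl": "no_wsfl", "no_wsfl": "no_wsfl",
    "2cqsl": "no_advgm", "no_advgm": "no_advgm",
    "3cqsl": "dice_ce", "dice_ce": "dice_ce", "dice+ce": "dice_ce",
    "4cqsl": "no_mim", "no_mim": "no_mim",
    "model-i": "model1", "model1": "model1", "gan": "model1",
    "model-ii": "model2", "model2": "model2", "gan+rec": "model2",
    "supervised": "supervised",
}


@dataclass(frozen=True)
class VariantFlags:
    use_wsfl: bool = True
    use_bfd: bool = True
    use_dice_ce: bool = False
    use_adv: bool = True
    gm_wrap: bool = True
    use_recon: bool = True
    use_vae: bool = True
    use_mim: bool = True
    # model I/II and the supervised baseline lack the disentangler block:
    # spatial features stay continuous (no straight-through binarization)
    use_disentangler: bool = True


def variant_flags(name: str) -> VariantFlags:
    key = VARIANT_ALIASES.get(name.strip().lower().replace(" ", ""))
    if key is None:
        raise ValueError(f"unrecognized variant {name!r}")
    table = {
        "full": VariantFlags(),
        "no_wsfl": VariantFlags(use_wsfl=False),
        "no_advgm": VariantFlags(gm_wrap=False),
        "dice_ce": VariantFlags(use_wsfl=False, use_bfd=False, use_dice_ce=True),
        "no_mim": VariantFlags(use_mim=False),
        "model1": VariantFlags(use_recon=False, use_vae=False, use_mim=False,
                               use_disentangler=False),
        "model2": VariantFlags(use_mim=False, use_disentangler=False),
        "supervised": VariantFlags(use_adv=False, use_recon=False,
                                   use_vae=False, use_mim=False,
                                   use_disentangler=False),
    }
    return table[key]


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 4
    learning_rate: float = 1e-4
    disc_learning_rate: float = 1e-4  # discriminators and MINE keep the
    # conventional rate even when the generator runs hotter at desk scale
    variant: str = "full"
    seed: int = 0
    steps_per_epoch: int | None = None
    grad_clip: float = 5.0
    augment: bool = True
    val_every: int = 1
    loss_weights: L.LossWeights = field(default_factory=L.LossWeights)
    focal: L.FocalParams = field(default_factory=L.FocalParams)
    gm: L.GMParams = field(default_factory=L.GMParams)
    recon: L.ReconParams = field(default_factory=L.ReconParams)
    net: NetConfig = field(default_factory=NetConfig)

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        variant_flags(self.variant)  # raises on unknown names


@dataclass
class TrainState:
    step: int = 0
    epoch: int = 0
    best_val_dice: float = -1.0
    best_params: dict | None = None
    history: list = field(default_factory=list)


def config_hash(cfg: TrainConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


# ----------------------------------------------------------------- internals
def _finite_or_raise(name: str, value: float) -> float:
    if not np.isfinite(value):
        raise RuntimeError(f"non-finite loss in term '{name}'")
    return float(value)


def _normalize_batch(images: np.ndarray) -> np.ndarray:
    return np.stack([pipeline.normalize_slice(s) for s in images])[:, None]


class _Streams:
    """Slice-level sampling of the labeled and unlabeled training pools."""

    def __init__(self, study: PhantomStudy, labeled_subjects, unlabeled_subjects,
                 cfg: TrainConfig, rng):
        self.study = study
        self.cfg = cfg
        self.rng = rng
        self.lab = [(s, f, k) for s in labeled_subjects
                    for f in range(study.images.shape[1])
                    for k in range(study.images.shape[2])]
        self.unl = [(s, f, k) for s in unlabeled_subjects
                    for f in range(study.images.shape[1])
                    for k in range(study.images.shape[2])]
        if not self.lab:
            raise ValueError("empty labeled set: at least one labeled training "
                             "subject is required")
        self._lab_ptr = 0
        self._lab_order = rng.permutation(len(self.lab))

    def _next_labeled(self):
        if self._lab_ptr >= len(self._lab_order):
            self._lab_ptr = 0
            self._lab_order = self.rng.permutation(len(self.lab))
        idx = self._lab_order[self._lab_ptr]
        self._lab_ptr += 1
        return self.lab[idx]

    def batches(self, n_steps: int):
        bs = self.cfg.batch_size
        for _ in range(n_steps):
            lab_ids = [self._next_labeled() for _ in range(bs)]
            unl_ids = [self.unl[i] for i in
                       self.rng.integers(0, len(self.unl), size=bs)]
            yield self._assemble(lab_ids, True), self._assemble(unl_ids, False)

    def _assemble(self, ids, labeled: bool):
        imgs, msks = [], []
        for s, f, k in ids:
            img = self.study.images[s, f, k]
            msk = self.study.masks[s, f, k] if labeled else None
            if self.cfg.augment:
                img, msk = augment(img, msk, self.rng)
            imgs.append(img)
            if labeled:
                msks.append(msk)
        batch = {"images": _normalize_batch(np.stack(imgs))}
        if labeled:
            batch["onehot"] = pipeline.one_hot(np.stack(msks))
        return batch


def _segmentation_loss(flags: VariantFlags, onehot, probs, cfg: TrainConfig):
    terms = []
    if flags.use_dice_ce:
        terms.append(L.soft_dice_ce(onehot, probs))
    if flags.use_wsfl:
        terms.append(L.weighted_soft_focal(onehot, probs, cfg.focal))
    if flags.use_bfd:
        terms.append(L.background_focal_dice(onehot, probs, cfg.focal.gamma,
                                             cfg.focal.epsilon))
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total


def train_step(nets: DisentangleNets, opts: dict, lab_batch: dict,
               unlab_batch: dict, cfg: TrainConfig, state: TrainState,
               rng) -> dict[str, float]:
    """One alternating update; returns the recorded loss values."""
    flags = variant_flags(cfg.variant)
    need_code = flags.use_recon or flags.use_vae or flags.use_mim
    need_unlabeled = flags.use_adv or need_code
    n_l = lab_batch["images"].shape[0]
    y_l = Tensor(lab_batch["onehot"])
    # one batched forward over both streams (labeled rows first)
    if need_unlabeled:
        x_all = Tensor(np.concatenate([lab_batch["images"],
                                       unlab_batch["images"]]))
    else:
        x_all = Tensor(lab_batch["images"])
    out = nets.forward_generator(x_all, with_reconstruction=need_code)
    probs_l = out["seg_probs"][:n_l]
    probs_u = out["seg_probs"][n_l:] if need_unlabeled else None
    logs: dict[str, float] = {}

    # (1) discriminator updates -------------------------------------------
    if flags.use_adv:
        for name, disc, probs in (("di", nets.di, probs_l),
                                  ("diu", nets.diu, probs_u)):
            opt = opts[name]
            opt.zero_grad()
            resid = L.lsgan_discriminator_residual(
                disc(probs.detach()), disc(y_l)
            )
            d_loss = L.adv_gm(resid, cfg.gm) if flags.gm_wrap else resid
            d_loss.backward()
            clip_grad_norm(disc.parameters(), cfg.grad_clip)
            opt.step()
            logs[f"loss_{name}"] = _finite_or_raise(name, d_loss.item())

    # (2) MINE statistic update -------------------------------------------
    pooled = z = None
    if flags.use_mim:
        pooled = nets.pooled_factor(out["factor"])
        z = out["code"].z
        perm = rng.permutation(pooled.shape[0])
        opt = opts["mine"]
        opt.zero_grad()
        joint = concat([pooled.detach(), z.detach()], axis=1)
        marg = concat([pooled.detach(), z.detach().index_select0(perm)], axis=1)
        mi_bound = L.mine_estimate(nets.mine, joint, marg)
        (-mi_bound).backward()
        clip_grad_norm(nets.mine.parameters(), cfg.grad_clip)
        opt.step()
        logs["mi_bound"] = _finite_or_raise("mine", mi_bound.item())

    # (3) main update ------------------------------------------------------
    zero = Tensor(np.float32(0.0))
    comp = {k: zero for k in ("adv_lab", "adv_unlab", "vae", "rec_lab",
                              "rec_unlab", "mim")}
    comp["seg_sup"] = _segmentation_loss(flags, y_l, probs_l, cfg)
    if flags.use_adv:
        res_l = L.lsgan_generator_residual(nets.di(probs_l))
        res_u = L.lsgan_generator_residual(nets.diu(probs_u))
        if flags.gm_wrap:
            res_l, res_u = L.adv_gm(res_l, cfg.gm), L.adv_gm(res_u, cfg.gm)
        comp["adv_lab"], comp["adv_unlab"] = res_l, res_u
    if flags.use_vae:
        comp["vae"] = L.kl_gaussian(out["code"].mu, out["code"].logvar)
    if flags.use_recon:
        comp["rec_lab"] = L.sl2sim(x_all[:n_l], out["recon"][:n_l], cfg.recon)
        comp["rec_unlab"] = L.sl2sim(x_all[n_l:], out["recon"][n_l:],
                                     cfg.recon)
    if flags.use_mim:
        perm2 = rng.permutation(pooled.shape[0])
        joint = concat([pooled, z], axis=1)
        marg = concat([pooled, z.index_select0(perm2)], axis=1)
        # MI is non-negative; a negative bound estimate is estimator noise
        # and must not keep degrading the code, so clamp at zero
        comp["mim"] = L.mine_estimate(nets.mine, joint, marg).maximum(zero)

    total = L.total_loss(comp, cfg.loss_weights)
    opts["gen"].zero_grad()
    total.backward()
    clip_grad_norm(nets.generator_parameters(), cfg.grad_clip)
    opts["gen"].step()

    for k, v in comp.items():
        logs[k] = _finite_or_raise(k, float(v.data))
    logs["total"] = _finite_or_raise("total", total.item())
    state.step += 1
    return logs


# ----------------------------------------------------------------- prediction
def preprocess_images(images: np.ndarray) -> np.ndarray:
    """Slice-wise normalization identical to the training pipeline."""
    flat = images.reshape(-1, *images.shape[-2:])
    return _normalize_batch(flat).reshape(*images.shape[:-2], 1, *images.shape[-2:])


def predict(nets: DisentangleNets, images: np.ndarray, batch_size: int = 8,
            normalize: bool = True) -> dict[str, np.ndarray]:
    """Deterministic inference: masks, reconstructions and both factors."""
    nets.eval()
    flat = np.asarray(images, dtype=np.float32).reshape(-1, *images.shape[-2:])
    if normalize:
        batched = _normalize_batch(flat)
    else:
        batched = flat[:, None]
    masks, recons, factors, mus = [], [], [], []
    for lo in range(0, batched.shape[0], batch_size):
        x = Tensor(batched[lo : lo + batch_size])
        out = nets.forward_generator(x, with_reconstruction=True)
        masks.append(np.argmax(out["seg_probs"].data, axis=1).astype(np.uint8))
        recons.append(out["recon"].data[:, 0])
        factors.append(out["factor"].hard.data)
        mus.append(out["code"].mu.data)
    lead = images.shape[:-2]
    return {
        "masks": np.concatenate(masks).reshape(*lead, *images.shape[-2:]),
        "recon": np.concatenate(recons).reshape(*lead, *images.shape[-2:]),
        "factor": np.concatenate(factors),
        "mu": np.concatenate(mus),
    }


def validation_dice(nets: DisentangleNets, study: PhantomStudy,
                    subjects) -> float:
    """Mean per-slice Dice over RV / myocardium / LV on given subjects."""
    scores = []
    for s in subjects:
        pred = predict(nets, study.images[s])["masks"]
        for f in range(study.images.shape[1]):
            for k in range(study.images.shape[2]):
                gt = study.masks[s, f, k]
                for cls in (1, 2, 3):
                    scores.append(dice(gt == cls, pred[f, k] == cls))
    return float(np.mean(scores))


# ------------------------------------------------------------------------ fit
@dataclass
class TrainResult:
    nets: DisentangleNets
    config: TrainConfig
    history: pd.DataFrame
    best_val_dice: float
    splits: dict


def fit(study: PhantomStudy, cfg: TrainConfig,
        out_dir: str | os.PathLike | None = None,
        splits: dict | None = None) -> TrainResult:
    """Train on a phantom study; keeps the best-on-validation parameters.

    The labeled pool is the intersection of the study's labeled subjects
    with the training split; the unlabeled pool is every other training
    subject.  With ``epochs=0`` the initialized model is returned untouched.
    """
    ss = np.random.SeedSequence(cfg.seed)
    data_rng, step_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
    net_cfg = replace(cfg.net, binarize=variant_flags(cfg.variant).use_disentangler)
    nets = DisentangleNets(net_cfg, seed=cfg.seed)
    if splits is None:
        splits = pipeline.split(study.n_subjects, seed=cfg.seed)
        # labels are a training resource: swap any labeled subject sitting in
        # val/test with an unlabeled training subject (deterministic)
        train = list(splits["train"])
        for part in ("val", "test"):
            part_ids = list(splits[part])
            for i, s in enumerate(part_ids):
                if study.labeled_flag[s]:
                    swap = next((t for t in train if not study.labeled_flag[t]),
                                None)
                    if swap is not None:
                        train[train.index(swap)] = s
                        part_ids[i] = swap
            splits[part] = np.sort(part_ids)
        splits["train"] = np.sort(train)
    labeled = [s for s in splits["train"] if study.labeled_flag[s]]
    unlabeled = [s for s in splits["train"] if not study.labeled_flag[s]]
    if not unlabeled:  # fully labeled study: both streams share the pool
        unlabeled = list(splits["train"])
    state = TrainState()
    opts = {
        "gen": Adam(nets.generator_parameters(), lr=cfg.learning_rate),
        "di": Adam(nets.di.parameters(), lr=cfg.disc_learning_rate),
        "diu": Adam(nets.diu.parameters(), lr=cfg.disc_learning_rate),
        "mine": Adam(nets.mine.parameters(), lr=10 * cfg.disc_learning_rate),
    }
    if cfg.epochs > 0:
        streams = _Streams(study, labeled, unlabeled, cfg, data_rng)
        n_steps = int(np.ceil(len(streams.unl) / cfg.batch_size))
        if cfg.steps_per_epoch is not None:
            n_steps = min(n_steps, cfg.steps_per_epoch)
        for epoch in range(cfg.epochs):
            nets.train()
            state.epoch = epoch
            epoch_logs = []
            for lab_batch, unlab_batch in streams.batches(n_steps):
                epoch_logs.append(
                    train_step(nets, opts, lab_batch, unlab_batch, cfg, state,
                               step_rng)
                )
            row = {k: float(np.mean([d[k] for d in epoch_logs]))
                   for k in epoch_logs[0]}
            row["epoch"] = epoch
            if (epoch + 1) % cfg.val_every == 0 or epoch == cfg.epochs - 1:
                row["val_dice"] = validation_dice(nets, study, splits["val"])
                if row["val_dice"] >= state.best_val_dice:
                    state.best_val_dice = row["val_dice"]
                    state.best_params = nets.state_dict()
            state.history.append(row)
    if state.best_params is not None:
        nets.load_state_dict(state.best_params)
    else:
        state.best_val_dice = validation_dice(nets, study, splits["val"])
    nets.eval()
    history = pd.DataFrame(state.history)
    result = TrainResult(nets=nets, config=cfg, history=history,
                         best_val_dice=state.best_val_dice, splits=splits)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        history.to_csv(os.path.join(out_dir, "training_log.csv"), index=False)
        save_checkpoint(os.path.join(out_dir, "checkpoint.npz"), nets, cfg)
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump({"seed": cfg.seed, "config_hash": config_hash(cfg),
                       "variant": cfg.variant,
                       "best_val_dice": state.best_val_dice}, fh, indent=2)
    return result


# ----------------------------------------------------------------- checkpoint
def save_checkpoint(path, nets: DisentangleNets, cfg: TrainConfig) -> None:
    meta = json.dumps({"train_config": asdict(cfg), "hash": config_hash(cfg)},
                      default=str)
    np.savez_compressed(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                        **nets.state_dict())


def load_checkpoint(path) -> tuple[DisentangleNets, TrainConfig]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    tc = meta["train_config"]
    cfg = TrainConfig(
        epochs=int(tc["epochs"]), batch_size=int(tc["batch_size"]),
        learning_rate=float(tc["learning_rate"]),
        disc_learning_rate=float(tc.get("disc_learning_rate", 1e-4)),
        variant=tc["variant"],
        seed=int(tc["seed"]),
        steps_per_epoch=None if tc["steps_per_epoch"] in (None, "None")
        else int(tc["steps_per_epoch"]),
        grad_clip=float(tc["grad_clip"]),
        augment=tc["augment"] in (True, "True"),
        val_every=int(tc["val_every"]),
        loss_weights=L.LossWeights(**{k: float(v) for k, v in
                                      tc["loss_weights"].items()}),
        focal=L.FocalParams(**{k: (v if k == "w_map" else float(v))
                               for k, v in tc["focal"].items()}),
        gm=L.GMParams(beta=float(tc["gm"]["beta"])),
        recon=L.ReconParams(
            alpha_l2=float(tc["recon"]["alpha_l2"]),
            ssim_window=int(tc["recon"]["ssim_window"]),
            ssim_k1=float(tc["recon"]["ssim_k1"]),
            ssim_k2=float(tc["recon"]["ssim_k2"]),
        ),
        net=NetConfig(
            base_filters=int(tc["net"]["base_filters"]),
            depth=int(tc["net"]["depth"]),
            latent_dim=int(tc["net"]["latent_dim"]),
            dropout=float(tc["net"]["dropout"]),
            seg_width=int(tc["net"]["seg_width"]),
            disc_filters=int(tc["net"]["disc_filters"]),
            si_input=tc["net"]["si_input"],
            binarize=tc["net"].get("binarize", True) in (True, "True"),
        ),
    )
    nets = DisentangleNets(
        replace(cfg.net, binarize=variant_flags(cfg.variant).use_disentangler),
        seed=cfg.seed,
    )
    nets.load_state_dict(state)
    nets.eval()
    return nets, cfg
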