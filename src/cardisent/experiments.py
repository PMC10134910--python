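"""Reference experiments on synthetic phantoms.

These functions bundle the package's headline computations into
reproducible, seeded runs: the low-label semi-supervised benchmark (the
full model against a GAN-only variant and a supervised-only baseline,
trained on a single labeled subject), reconstruction quality and the
style-swap disentanglement probe on the held-out subjects, ejection-
fraction recovery from rasterized masks, and the Gaussian
mutual-information recovery study for the MINE estimator.

Problem sizes default to a desk scale that a single CPU core handles in
minutes; they are the sizes quoted in the documentation.
"""

from __future__ import annotations

import numpy as np

from . import losses as L
from . import pipeline
from .evaluation import dice, psnr_cc
from .networks import MineStatistic, NetConfig
from .nn import Adam, Tensor
from .phantom import PhantomConfig, PhantomStudy, generate_study
from .trainer import TrainConfig, TrainResult, fit, predict

DESK_NET = dict(base_filters=8, seg_width=32, disc_filters=8, latent_dim=8)


# ----------------------------------------------------------- low-label study
def lowlabel_study(seed: int, image_size: int = 32, n_subjects: int = 100,
                   n_slices: int = 3, label_fraction: float = 0.01,
                   noise_sigma: float = 0.03) -> tuple[PhantomStudy, dict]:
    """Generate the benchmark study and pin its labeled subjects.

    The labeled subset (round(label_fraction * n_subjects), at least one
    subject) is drawn from the *training* split so the semi-supervised
    trainer always sees it; validation/test subjects are never labeled.
    """
    cfg = PhantomConfig(image_size=image_size, n_subjects=n_subjects,
                        n_slices=n_slices, label_fraction=label_fraction,
                        noise_sigma=noise_sigma, seed=seed)
    study = generate_study(cfg)
    splits = pipeline.split(n_subjects, seed=seed)
    n_lab = max(1, int(round(label_fraction * n_subjects)))
    rng = np.random.default_rng(seed + 1)
    labeled = rng.choice(splits["train"], size=n_lab, replace=False)
    study.labeled_flag[:] = False
    study.labeled_flag[labeled] = True
    study.truth["labeled"] = study.labeled_flag
    return study, splits


def benchmark_config(seed: int, variant: str, epochs: int = 40,
                     steps_per_epoch: int = 30) -> TrainConfig:
    return TrainConfig(
        epochs=epochs, batch_size=4, variant=variant, seed=seed,
        steps_per_epoch=steps_per_epoch, val_every=5, learning_rate=3e-4,
        net=NetConfig(**DESK_NET),
    )


def train_variant(study: PhantomStudy, splits: dict, seed: int, variant: str,
                  epochs: int = 40, steps_per_epoch: int = 30) -> TrainResult:
    cfg = benchmark_config(seed, variant, epochs, steps_per_epoch)
    return fit(study, cfg, splits=splits)


def heldout_dice(result: TrainResult, study: PhantomStudy,
                 subjects) -> dict[str, float]:
    """Per-structure and mean Dice over all slices of the given subjects."""
    per_class = {"RV": [], "Myo": [], "LV": []}
    for s in subjects:
        pred = predict(result.nets, study.images[s])["masks"]
        for f in range(study.images.shape[1]):
            for k in range(study.images.shape[2]):
                gt = study.masks[s, f, k]
                for name, cls in (("RV", 1), ("Myo", 2), ("LV", 3)):
                    per_class[name].append(dice(gt == cls, pred[f, k] == cls))
    out = {k: float(np.mean(v)) for k, v in per_class.items()}
    out["mean"] = float(np.mean(list(out.values())))
    return out


def reconstruction_quality(result: TrainResult, study: PhantomStudy,
                           subjects) -> dict[str, float]:
    """PSNR (dB) and Pearson correlation of held-out reconstructions.

    Reconstructions approximate the *normalized* inputs, so quality is
    measured against the same slice-normalized images the model sees.
    """
    psnrs, ccs = [], []
    for s in subjects:
        imgs = study.images[s]
        ref = np.stack([pipeline.normalize_slice(x)
                        for x in imgs.reshape(-1, *imgs.shape[-2:])])
        rec = predict(result.nets, imgs)["recon"].reshape(ref.shape)
        for x, r in zip(ref, rec):
            p, c = psnr_cc(x, r)
            if np.isfinite(p):
                psnrs.append(p)
            if np.isfinite(c):
                ccs.append(c)
    return {"psnr_db": float(np.mean(psnrs)), "cc": float(np.mean(ccs))}


def swap_test(result: TrainResult, study: PhantomStudy, subjects) -> dict:
    """Exchange sentiency codes across scanner domains on held-out slices.

    Reports the mean absolute shift of reconstruction intensity under a
    cross-domain z swap relative to a within-domain swap, and the fraction
    of segmentation pixels whose label changes when z changes.
    """
    nets = result.nets
    nets.eval()
    subjects = list(subjects)
    dom = study.domain_id
    by_domain = {d: [s for s in subjects if dom[s] == d] for d in (0, 1)}
    if not by_domain[0] or not by_domain[1]:
        raise ValueError("swap test needs held-out subjects from both domains")

    def forward(img2d):
        x = Tensor(pipeline.normalize_slice(img2d)[None, None])
        factor = nets.skeleton(x)
        code = nets.sentiency(x, factor)
        return x, factor, code

    def recon_with(factor, code_other):
        film_out, film_pen = nets.film(factor, code_other)
        spade = nets.spade(code_other, factor)
        rec = nets.recon(film_out, spade)
        seg = nets.seg(nets.segmentor_input(factor, film_pen))
        return rec.data[0, 0], np.argmax(seg.data, axis=1)[0]

    cross_shifts, within_shifts, mask_changes = [], [], []
    k_mid = study.images.shape[2] // 2
    for s in by_domain[0][:4]:
        for t_cross, t_within in zip(by_domain[1][:4], by_domain[0][1:5]):
            xa, fa, ca = forward(study.images[s, 0, k_mid])
            _, _, cb = forward(study.images[t_cross, 0, k_mid])
            _, _, cw = forward(study.images[t_within, 0, k_mid])
            rec_own, seg_own = recon_with(fa, ca)
            rec_cross, seg_cross = recon_with(fa, cb)
            rec_within, seg_within = recon_with(fa, cw)
            cross_shifts.append(abs(rec_cross.mean() - rec_own.mean()))
            within_shifts.append(abs(rec_within.mean() - rec_own.mean()))
            mask_changes.append(np.mean(seg_cross != seg_own))
            mask_changes.append(np.mean(seg_within != seg_own))
    cross = float(np.mean(cross_shifts))
    within = float(np.mean(within_shifts))
    return {
        "cross_domain_shift": cross,
        "within_domain_shift": within,
        "shift_ratio": cross / max(within, 1e-9),
        "mask_change_fraction": float(np.mean(mask_changes)),
    }


# ------------------------------------------------------------- EF recovery
def ef_recovery(seed: int, image_size: int = 192, n_subjects: int = 4,
                n_slices: int = 8) -> dict[str, float]:
    """Ejection fraction from Simpson volumetry of rasterized ground-truth
    masks versus the analytic truth of the generating geometry."""
    from .evaluation import clinical_indices

    cfg = PhantomConfig(image_size=image_size, n_subjects=n_subjects,
                        n_slices=n_slices, label_fraction=0.5, seed=seed)
    study = generate_study(cfg)
    errors = []
    for s in range(n_subjects):
        idx = clinical_indices(study.masks[s, 0], study.masks[s, 1],
                               cfg.pixel_spacing, cfg.slice_thickness)
        truth_ef = study.truth.loc[s, "ef"]
        errors.append(abs(idx.ef_percent - truth_ef))
    return {"max_abs_ef_error": float(np.max(errors)),
            "mean_abs_ef_error": float(np.mean(errors)),
            "n": n_subjects}


# ------------------------------------------------------ Gaussian MI recovery
def gaussian_mi_true(rho: float) -> float:
    return -0.5 * float(np.log(1.0 - rho**2))


def mine_gaussian_benchmark(rho: float, seed: int, n: int = 10_000,
                            steps: int = 400, batch: int = 512,
                            lr: float = 1e-3) -> float:
    """Train a MINE statistic network on correlated bivariate Gaussians and
    return the mutual-information estimate (nats) on the full sample."""
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    sample = rng.multivariate_normal([0, 0], cov, size=n).astype(np.float32)
    net = MineStatistic(rng=rng, in_dim=2, hidden=64)
    opt = Adam(net.parameters(), lr=lr)
    for _ in range(steps):
        idx = rng.integers(0, n, size=batch)
        a, b = sample[idx, :1], sample[idx, 1:]
        perm = rng.permutation(batch)
        joint = np.concatenate([a, b], axis=1)
        marg = np.concatenate([a, b[perm]], axis=1)
        mi = L.mine_estimate(net, Tensor(joint), Tensor(marg))
        opt.zero_grad()
        (-mi).backward()
        opt.step()
    # evaluate on the full sample, averaging over a few permutations
    estimates = []
    for _ in range(8):
        perm = rng.permutation(n)
        joint = np.concatenate([sample[:, :1], sample[:, 1:]], axis=1)
        marg = np.concatenate([sample[:, :1], sample[perm, 1:]], axis=1)
        estimates.append(L.mine_estimate(net, Tensor(joint), Tensor(marg)).item())
    return float(np.mean(estimates))
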