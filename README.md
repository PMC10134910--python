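# cardisent

Semi-supervised segmentation and reconstruction of short-axis cardiac
cine-MR slices through **content/style disentanglement**, exercisable
end-to-end on synthetic multi-domain cardiac phantoms — no external dataset
or GPU required.

## Who this is for

Researchers studying label-efficient medical image segmentation: the
package implements a full semi-supervised pipeline that learns from a
handful of labeled subjects plus many unlabeled ones acquired on different
scanners, and lets every component (losses, conditioning layers,
mutual-information estimator, training loop, clinical metrics) be tested
against analytic ground truth.

## The model

Each image `x` is factorized into

- a **spatial factor** `f_SK ∈ {0,1}^{H×W×8}` — near-binary anatomy maps
  from a nested-skip encoder with normalized-projection skips and eight
  bottleneck decoders, binarized by straight-through rounding; and
- a **sentiency code** `z ∈ R^8` — a VAE latent (μ, log σ²; z = μ + σ⊙ε)
  capturing scanner appearance (intensity, contrast, bias).

Segmentation is `SI(f_SK)` (softmax over background/RV/myocardium/LV), so
masks are independent of style by construction. Reconstruction re-entangles
the factors through a FiLM-conditioned stack (per-channel `γ(z)·F + β(z)`)
and a SPADE decoder (instance-normalized features re-modulated spatially by
`γ(f_SK), β(f_SK)`), fused by a 1×1 convolution.

Training minimizes

```
L = λ_seg·L_WSBF + λ_advGM·(L_adv^lab + L_adv^unlab) + λ_vae·KL
    + λ_SL2SIM·(L_rec^lab + L_rec^unlab) + λ_MIM·MI(f_SK, z)
```

with λ = (10, 10, 0.01, 0.01, 1): a weighted soft background focal loss for
supervision, least-squares adversarial residuals under a Geman–McClure
saturation `N/(2β+N)` for both streams, Gaussian KL to the unit prior,
`1 − SSIM + α‖x − x̂‖²` for reconstruction, and a MINE (Donsker–Varadhan)
mutual-information bound minimized between the factors. Ablation variants
(`no_wsfl`, `no_advgm`, `dice_ce`, `no_mim`, `model1`, `model2`,
`supervised`) gate individual terms.

Everything runs on a small numpy reverse-mode autodiff engine
(`cardisent.nn`) written for this package; gradients are verified against
finite differences in the test suite.

## Worked example

Generate a phantom study with analytic ground truth and recover the
clinical indices from Simpson volumetry of its masks:

```python
from cardisent.phantom import PhantomConfig, generate_study
from cardisent.evaluation import clinical_indices, evaluate_masks, summarize

cfg = PhantomConfig(image_size=192, n_subjects=4, n_slices=8,
                    label_fraction=0.5, seed=7)
study = generate_study(cfg)

idx = clinical_indices(study.masks[0, 0], study.masks[0, 1],
                       cfg.pixel_spacing, cfg.slice_thickness)
truth = study.truth.loc[0]
print(f"subject 0: EDV {idx.lvv_ml:.1f} mL (truth {truth.edv/1e3:.1f}), "
      f"EF {idx.ef_percent:.1f}% (truth {truth.ef:.1f}%), "
      f"myo mass {idx.myo_mass_g:.1f} g")

noisy = study.masks[0, 0].copy()
noisy[:, ::17, :] = 0   # corrupt the prediction a little
report = evaluate_masks(study.masks[0, 0], noisy, spacing=cfg.pixel_spacing)
print(summarize(report).round(3).to_string(index=False))
```

prints

```
subject 0: EDV 136.3 mL (truth 136.2), EF 60.6% (truth 60.6%), myo mass 219.8 g
structure  dice_mean  dice_std  jaccard_mean  hausdorff_mean  precision_mean  recall_mean
       LV      0.969     0.004         0.939          13.983             1.0        0.939
      Myo      0.969     0.006         0.941           5.878             1.0        0.941
       RV      0.967     0.004         0.936           9.844             1.0        0.936
```

EF from rasterized masks matches the analytic truth of the generating
geometry to a tenth of a percentage point at this resolution; the corrupted
prediction loses recall but not precision, and the dropped rows show up in
the Hausdorff distances (mm).

To train the semi-supervised model from the command line on a generated
study (one labeled subject, two scanner domains):

```bash
cardisent train --out runs/demo --n-subjects 100 --image-size 32 \
    --n-slices 3 --label-fraction 0.01 --epochs 20 --seed 1
```

which writes `training_log.csv`, `checkpoint.npz` and a `run_manifest.json`
with the seed and config hash; `cardisent segment` / `reconstruct` /
`evaluate` consume the checkpoint and NIfTI volumes.

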