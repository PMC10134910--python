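# Methods

## Problem and model

`cardisent` performs semi-supervised segmentation of short-axis cardiac
cine-MR slices (background, right ventricle, LV myocardium, LV blood pool)
together with image reconstruction, under the assumption that images from
different scanners share a common *spatial* space (anatomy) but differ in
*non-spatial* space (intensity, contrast, bias field). The model decomposes
each slice into:

- a **spatial factor** `f_SK`: an 8-channel near-binary map produced by a
  nested-skip (U-Net++-style) encoder whose skip connections are replaced by
  normalized 1×1 projections (pooled batch+instance variance, learned
  affine, 1×1 convolution, multiplicative Gaussian dropout), with eight
  lightweight decoders attached at the bottleneck, one sigmoid channel each.
  Channels are binarized by straight-through rounding at 0.5: the forward
  value is hard {0,1}, the gradient flows through the sigmoid.
- a **sentiency code** `z` (default width 8): a convolutional VAE encoder
  over the (image, `f_SK`) pair yields a Gaussian posterior (μ, log σ²); z
  is sampled by the reparameterization trick during training and set to μ at
  evaluation. The posterior is initialized narrow (log σ² bias −2) so the
  code is not drowned in sampling noise before the decoders learn to read
  it; the KL term pulls σ back toward the unit prior. The encoder contains
  no normalization layers: batch or instance statistics would strip exactly
  the global intensity and contrast information the style code must
  capture.

Segmentation is a three-convolution softmax head applied to the hard
spatial factor (`SI(f_SK)`), so predicted masks are independent of the
style code by construction; a configuration switch (`si_input="film"`)
instead feeds the FiLM decoder's penultimate features. Reconstruction
re-entangles the factors through two conditioned decoders — a FiLM stack
(8,8,8,8,1 channels, 3×3, stride 1, batch-norm + leaky-ReLU, per-layer
γ/β predicted from z, initialized at the identity) and a SPADE decoder
(shape-aware denormalization: instance-normalized features re-modulated by
γ(f_SK), β(f_SK) from three convolutions on the hard factor, plus a
z-conditioned scale/shift on the normalized statistics) — fused by channel
concatenation, a 1×1 convolution and a sigmoid.

A detail that matters: the SPADE decoder's input projects z onto a coarse
4×4 spatial grid before upsampling. Broadcasting z to a spatially constant
field would be annihilated by the first instance normalization, severing
the style path entirely.

## Objectives

With labeled pairs (x_l, y_l) and unlabeled images x_u:

- **Supervised segmentation (WSBF)** = weighted soft focal loss (mean of
  (α₀ + y(α₁−α₀))·|y−ŷ|^γ·w·CE(y,ŷ)) plus the background focal dice term
  (per class, [2 − dice(y_c,ŷ_c) − dice(1−y_c,1−ŷ_c)]^{1/γ}, summed). The
  per-pixel weight map w is the per-class inverse frequency within the
  batch, normalized to mean 1 (the imbalance-correction reading of its
  stated purpose); α₀=0.25, α₁=0.75, γ=2 follow the focal-loss convention
  within the stated γ∈[1,3] range; dice smoothing ε=1e−6.
- **Adversarial (adv-GM)**: least-squares GAN residuals passed through the
  Geman–McClure saturation N/(2β+N), β=0.5. Two discriminators of identical
  DCGAN-like shape score labeled-stream and unlabeled-stream predictions;
  "real" for both is the labeled ground-truth one-hot mask.
- **VAE KL**: closed-form Gaussian KL to the unit prior, averaged over both
  streams.
- **Reconstruction (SL2SIM)**: 1 − SSIM (Gaussian window 7, σ=1.5, k₁=0.01,
  k₂=0.03, data range 1) + α·mean squared error with α=1 (the mean, not the
  sum, so the term is image-size invariant).
- **Mutual-information minimization (MIM)**: a Donsker–Varadhan (MINE)
  bound between the spatially pooled soft factor and z, estimated by a
  3-layer perceptron. The statistic network is updated to maximize the
  bound (its own optimizer, 10× the base learning rate — MLP statistics
  need faster steps than the convolutional nets); the encoders receive the
  minimization gradient. Marginal samples are in-batch permutations of z;
  the log argument is clamped at 1e−8.

The total is the weighted sum with λ_seg=10, λ_adv-GM=10, λ_vae=0.01,
λ_SL2SIM=0.01, λ_MIM=1. Each step runs, in order: discriminator updates
(labeled, then unlabeled), the MINE update, then one generator update;
discriminators, the statistic network and the generator never share an
optimizer step. Adam (β₁=0.9, β₂=0.999), gradient clipping at global norm
5 to stabilize the adversarial min-max at CPU scale. NaN in any term aborts
with the offending term named.

The MIM term entering the total objective is clamped at zero: mutual
information is non-negative, so a negative bound estimate is estimator
noise and must not keep degrading the code.

Ablation variants gate terms exactly (disabled terms enter as literal
zeros, so they contribute no gradient): `no_wsfl` (focal dice only),
`no_advgm` (plain least-squares adversarial loss), `dice_ce` (Dice+CE
supervision), `no_mim` (keeps the disentangler, drops MIM), `model1` (GAN
path only), `model2` (GAN + reconstruction), `supervised` (supervision
only). `model1`, `model2` and `supervised` additionally lack the
*disentangler block*: their spatial features stay continuous (no
straight-through binarization), mirroring the incremental architectural
decomposition they ablate rather than a loss-only gating.

## Synthetic phantoms

The generator emulates a multi-scanner cine-MR study: per subject a
concentric LV blood pool (disk) and myocardial annulus with an abutting RV
crescent at a uniformly random in-plane orientation, the heart centre
wandering by ±4% of the field of view, radii spanning wide per-subject
ranges and tapering linearly toward the apex (scale 0.30–0.55), and
contraction from ED to ES (LV pool ×0.55–0.75, RV ×0.65–0.85, epicardium
×0.95 so the wall thickens). The orientation and size dispersion matter:
without them a single labeled subject plus augmentation suffices for any
baseline, and the semi-supervised comparison degenerates. Two scanner domains differ in class mean
intensities, contrast exponent, and a smooth random polynomial bias field;
Gaussian noise (σ=0.03) is added and intensities clipped to [0,1].

The background is not empty: per subject, 2–5 mid-intensity ellipses
(levels 0.30–0.65, overlapping the myocardium/RV means; radii 4–9% of the
field of view) stand in for the non-cardiac anatomy that surrounds the
heart in real short-axis images. They are rendered on background pixels
only and persist across slices and frames. Without them the four classes
are separable by intensity alone and a supervised baseline trained on a
single subject generalizes anyway, making the semi-supervised comparison
vacuous; with them, shape context learnable from unlabeled data is
genuinely required.

Two
frames (ED/ES) per subject suffice for EDV/ESV/EF; ground-truth volumes are
computed analytically from the continuous geometry (disk and circle-lens
areas), never from rasterized masks. Label convention {0,1,2,3} =
{background, RV, myocardium, LV}. Augmentation applies, each with
probability 1/2: rotation ≤90°, zoom ≤20%, shifts ≤20%, horizontal/vertical
flips (geometric transforms identical for image and mask, bilinear vs
nearest) and additive noise on the image only.

What the phantoms do **not** emulate: MR physics (k-space artifacts, Rician
noise), pathology subgroups, papillary muscles, through-plane motion, or
realistic anatomical variability. Passing benchmarks here demonstrates that
the optimization and disentanglement mechanics work, not clinical-grade
accuracy on real cine-MR.

## Preprocessing

Slice-wise normalization subtracts the slice mean and divides by the
intensity range, then min–max rescales to [0,1] (both printed constraints —
mean-subtracted numerator and [0,1] range — are then satisfied); constant
slices map to zeros. In-plane resampling targets 1.37 mm/pixel (bilinear
images, nearest masks; through-plane spacing untouched). Crop/pad is
center-anchored, 0-based half-open. Splits are subject-level, 70/15/15 by
default, floor for val/test with the remainder to train. When the trainer
computes its own split it moves labeled subjects into the training
partition (labels are a training resource); explicitly supplied splits are
used verbatim.

## Desk-scale benchmark conditions

The reference low-label benchmark trains on 100 subjects, 3 slices, 2
frames at 32×32 with exactly one labeled subject (1%), nets at 8 base
filters (segmentor width 32, discriminator 8), batch 4, 40 epochs × 30
steps. These sizes are the package's CPU desk scale: they keep a full
three-variant comparison (full / GAN-only / supervised) in minutes on one
core while preserving the study's structure (two domains, 1% labels,
held-out subjects from both domains). The generator learning rate is
raised to 3e-4 (from the 1e-4 default appropriate to paper-scale
networks) because much smaller networks and images converge substantially
faster at a larger step size; the discriminators and the MINE statistic
network stay at 1e-4, which measurably stabilizes the adversarial
min-max at this scale.

A consequence of the 32×32 grid deserves emphasis: the myocardial wall
rasterizes to 1–2 pixels, which bounds the overlap any method — however
well trained — can achieve on that structure. Desk-scale Dice values are
therefore substantially below what the same architecture attains on
full-resolution images and should be read comparatively (between
variants), not as absolute quality.

## Numerical choices

- Probabilities are clamped to [1e−7, 1−1e−7] before logarithms.
- Instance/batch variances carry an ε=1e−5 floor; the focal-dice base is
  clamped at 0 (+1e−12 inside the 1/γ power to keep its gradient finite).
- Dice/Jaccard/precision/recall of two empty masks are defined as 1 so
  per-slice averages over apical slices with absent structures are
  well-defined; the Hausdorff distance of an empty mask raises instead.
- Hausdorff is the full maximum over 4-connectivity boundary pixels,
  computed per 2-D slice (Euclidean distance transform, scaled by pixel
  spacing), and is verified against an O(n²) pairwise reference.
- Simpson volumetry is pixel count × spacing² × thickness per slice.
- Myocardial mass uses 1.06 g/cm³ on the ED myocardial volume.
- EvoNorm projection pools batch and instance variance additively under the
  square root; running batch variance makes evaluation deterministic.
- All arrays are float32; reductions over batches are means.

## Known limitations

- The numpy autodiff engine is single-threaded and eager; paper-scale
  widths (64 base filters, 192×192) are configurable but impractically slow
  on CPU.
- MINE estimates carry the usual Donsker–Varadhan bias/variance; the
  Gaussian recovery study (N=10⁴) bounds it empirically at ≲0.05 nats.
- `model2` differs from the paper's architectural reading (see variant
  note above).
- The Hausdorff metric offers a per-slice 2-D computation only; a 3-D
  variant would need anisotropic sampling support.
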