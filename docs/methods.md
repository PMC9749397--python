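# Methods

This note documents the models, conventions and numerical choices behind
`sbpet`, in the order the pipeline runs them.

## Problem setting

FDG-PET reads out regional glucose metabolism; neurodegeneration shows up
as focal or regional *hypometabolism*. Template-based comparisons (subject
vs. population atlas) break down under atrophy, because a deformed anatomy
is compared against an average one. The approach implemented here sidesteps
the template: a conditional generative model, trained only on cognitively
normal subjects, synthesizes from each subject's own T1w MRI the FDG-PET
that subject *would* show if metabolically healthy (the synthetic baseline,
sbPET). Abnormality is then the voxel-wise relative deviation of the true
PET from this personalized baseline.

## Phantom simulator

Real paired PET/MRI cohorts of the kind this method is built for are
access-restricted, so the package ships a simulator that reproduces the
statistical structure the pipeline depends on, with analytically known
ground truth:

* **Anatomy** — three concentric deformed ellipsoids: CSF ventricle core,
  WM shell, GM cortical ribbon. A per-subject smooth random radial
  perturbation field (coarse 5-cell grid, cubic-upsampled, default peak
  amplitude 0.05 of the radius) provides inter-subject morphological
  variability. Tissue probabilities ramp linearly over a 2-voxel shell at
  each boundary, so partial-volume voxels exist and the GM/WM-conditioned
  normalization rules are exercised non-trivially.
* **Atrophy** `a in [0,1]` — ventricle radius grows linearly (up to +80% at
  `a=1`) and the GM ribbon thins linearly (up to −55%). Both are monotone
  by construction, which the tests verify by counting majority-probability
  voxels. Atrophy deforms anatomy only; per-tissue metabolic rates are
  untouched, so PET regenerates consistently.
* **Uptake** — PET is the probability-weighted mix of per-tissue rates,
  default GM:WM:CSF = 3.0:1.0:0.2 (the familiar strong GM-dominant FDG
  contrast). MRI is the probability-weighted mix of per-tissue means
  (GM 0.55, WM 0.85, CSF 0.15, arbitrary units, T1w-like ordering) plus
  smooth per-tissue texture with the configured SDs.
* **Degradations** — a multiplicative low-frequency bias field on the MRI
  (coarse 4-cell grid upsampled; exact range `[1−A, 1+A]`, mean exactly 1),
  then additive Gaussian noise on both modalities (default SD 0.02 in
  uptake units ≈ 0.7% of GM uptake); PET is clipped at 0.
* **Lesions** — spheres with known center/radius in which uptake is
  multiplied by `(1 − reduction)`, by default restricted to GM voxels
  (probability > 0.5). MRI is unchanged: metabolic change without
  structural change, the regime in which a personalized baseline is
  needed. The affected voxel set is stored as the ground-truth lesion mask.
* **Atlas** — eight octant labels around the grid center; enough regions
  to exercise every per-region code path without pretending to be a real
  parcellation.

What the phantoms do **not** model: MRI physics (no k-space artifacts, no
Rician noise), PET counting statistics, registration error, real cortical
folding. Passing phantom tests therefore demonstrates correctness of the
operators and trainability of the model under controlled conditions — not
clinical performance.

## Preprocessing conventions

Volumes arrive co-registered, skull-stripped and segmented (phantoms are
generated that way; clinical use would delegate those steps to standard
external tools).

* **Mask dilation**: Euclidean distance transform thresholded at the metric
  radius (default 10 mm), honoring anisotropic spacing. Matches brute-force
  distance enumeration exactly.
* **MRI z-normalization**: mean/SD from voxels with GM+WM probability
  > 0.5 only (population SD). Restricting the statistics to tissue keeps
  the scale stable under atrophy, which changes the CSF fraction. Voxels
  outside the *dilated* mask are set to the sentinel −7 exactly, so the
  network can distinguish "unmasked" from "dark tissue".
* **PET normalization**: divide by the mean of the top-2% GM/WM voxels of a
  3 mm-FWHM blurred copy. The top fraction is voxels at or above the 98th
  linear-interpolation percentile, ties included; selection *and* averaging
  use the blurred values, while the returned volume is the unblurred PET
  over the constant. The divisor is retained for denormalization to
  MBq/ml. "3 mm gaussian" is interpreted as FWHM (the PET post-filter
  idiom), σ = 3/(2√(2 ln 2)) ≈ 1.274 mm.
* **Crop/pad to a cube**: centered per axis; odd remainders put the larger
  share on the high-index side (fixed so the operation is bit-exactly
  testable). The affine origin shifts so retained voxels keep their world
  coordinates.

## Model

Two stacked Pix2Pix-style conditional GANs share one architecture family:

* **Generators**: symmetric 3-D U-Nets (two 3³ convolutions per encoder
  level, stride-2 convolution downsampling, nearest-upsample + convolution
  decoding with skip concatenation, linear 1×1×1 head, LeakyReLU 0.2). The
  sketcher maps the MRI patch to a PET draft; the refiner receives the MRI
  patch concatenated with the (detached) sketch — anatomical conditioning
  is preserved and no gradients flow from refiner to sketcher, the
  standard stabilization for stacked GANs.
* **Discriminators**: 3-D PatchGANs over (MRI, candidate-PET) channel
  pairs, a stack of stride-2 convolutions ending in per-patch sigmoid
  probabilities. Each stage keeps its own discriminator, updated
  alternately with its generator every step.
* **Losses**: BCE adversarial terms (probabilities clamped to
  [1e−7, 1−1e−7]); brain-mask-confined L1 recognition loss; for the
  refiner an additional GM-masked L1 (GM probability > 0.5) emphasizing
  the tissue where neurodegeneration lives. Default weights λ_adv = 1,
  λ_L1 = λ_GM = 100 (Pix2Pix convention). All losses ignore everything
  outside their masks, including the −7 sentinel region.
* **Optimization**: Adam (0.9/0.999), batch size 2, piecewise-constant
  learning rate decayed 10× at fixed steps. The full-scale schedule is
  90,000 pretraining steps (decays at 20,000 and 50,000, lr₀ 1e−4) and
  60,000 fine-tuning steps — transfer learning from a large heterogeneous
  cohort to a smaller high-resolution one. Holdout L1 is validated
  periodically and the best-scoring weights are kept (early stopping).
* **Augmentation** (training only): sagittal mirroring (p = 0.5), per-axis
  affine scale ~ U(0.9, 1.1) and rotation ~ U(−10°, 10°) (p = 1), and a
  multiplicative bias field on the MRI inside the brain (p = 0.5). One
  geometric transform is applied to images (linear resampling) and masks
  (nearest) identically.

### Desk preset

The numpy backend computes convolutions as im2col GEMMs with hand-written
backpropagation (gradient-checked against finite differences). For a
single CPU core the desk preset narrows the problem: U-Net depth 3 with 6
base channels, PatchGAN with 3 levels, patches of 8 neighboring full
sagittal slices, phantom grids of 32³, and schedules of a few thousand
steps with lr₀ = 1e−3 and 10× decays at 3/4 and 7/8 of training (both
choices selected on holdout validation L1). The raised learning rate is
deliberate: at 2,000 Adam steps the full-scale 1e−4 moves He-initialized
weights only a few percent of their scale, which cannot leave the
constant-predictor regime; 1e−3 restores a comparable *total* parameter
displacement to a much longer low-rate schedule, and the late decays keep
most of the short budget at the productive rate (the best-validation
checkpoint restore guards the post-decay tail). Augmentation is off by default at desk
scale — with deterministic phantom uptake and short schedules it slows
convergence; it earns its cost on the full-length schedules. The `full`
preset (depth 5, 56 base channels, 4 PatchGAN levels) instantiates the
~200 M-parameter budget of the full-scale model and is used for
architecture accounting only.

## Patch inference and fusion

Whole volumes are synthesized by running every stride-1 sagittal patch
position (S − w + 1 of them; a `drop_last` switch reproduces an S − w
convention) through sketcher and refiner, then fusing overlaps with
weights that decay with the slice's distance to its patch center:
triangular profile `w(o) = (w/2 + 0.5) − |o − (w−1)/2|`, strictly positive
so every covering patch contributes and the per-voxel weighted mean is
well defined everywhere (per-voxel denominator normalization keeps volume
edges exact). Fusing the patches extracted from any volume reproduces that
volume to 1e−12 — the partition-of-unity contract that pins the scheme
down. Gaussian and uniform profiles are available alternatives.

## Abnormality mapping

Given true PET `Y` and synthetic baseline, the sbPET is first
*post-normalized*: scaled so its mean over the subject's healthy-uptake
region (GM/WM voxels in the top 2% of 3 mm-blurred true-PET uptake)
matches the true PET's. Both volumes are then blurred (3 mm) and

    Z%(x) = (Y(x) − Ŷ(x)) / Ŷ(x) · 100%

is evaluated inside the brain mask wherever the blurred baseline exceeds
1e−6 of its within-brain mean; other voxels are carried as NaN and
excluded from every summary (reported as empty, never as zero). Negative
Z% is hypometabolism. Group maps average voxel-wise over the maps in which
each voxel is defined. Z% is invariant to joint rescaling of `Y` and the
sbPET, since post-normalization cancels any common scale.

Extreme Z% values can occur where the baseline is small (wide CSF spaces);
the package does not clip them — they are visible in the map, and the NaN
rule only removes near-zero denominators.

## Evaluation metrics

PSNR uses the mask-restricted MSE with the peak taken as the maximum of
the *true* image within the mask — this makes the metric invariant to
joint rescaling, as required for comparability across PET normalization
choices. RD% (signed, positive = overestimation) and Abs% average the
relative difference over mask voxels whose true value exceeds a floor of
1% of the within-mask mean (guarding against near-zero CSF denominators).
The joint-uptake fit is ordinary least squares of synthetic on true with
R² the squared Pearson correlation. Each metric is tested against an
independent brute-force loop implementation at 1e−10.

## Problem sizes used by the shipped runs

The end-to-end acceptance check trains on 40 healthy phantoms (grid 32³)
for 2,000 steps and evaluates 5 healthy plus 5 lesioned (40% reduction)
holdout subjects. The acceptance script runs the full two-stage pipeline
(30 pretraining + 10 fine-tuning subjects, 900 + 400 steps, 4 + 4
holdouts) plus a network-free ground-truth recovery: with the
pre-injection healthy PET as the baseline and blur disabled, the mean Z%
over an injected 30%-reduction lesion core reads −30% to numerical
precision. These sizes are the package's desk-scale defaults; the full
protocol (192³ grids, 90k/60k steps, ~200 M parameters) is expressed in
the same configuration objects.

## Known limitations

* The numpy backend is single-threaded and CPU-bound; full-scale training
  is out of reach by design (the architecture and schedules are still
  faithfully represented and unit-tested).
* Phantom realism bounds what desk-scale results can claim: Abs% on
  phantom holdouts reflects tissue-contrast learnability, not clinical
  synthesis accuracy.
* Registration, bias correction, skull-stripping and segmentation are out
  of scope; inputs must arrive aligned and segmented.
* The simulator's lesions are metabolic only; structural lesion modeling
  (e.g. atrophy coupled to hypometabolism) is not attempted.
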