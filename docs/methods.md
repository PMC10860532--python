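# Methods

`decontrast3d` synthesizes virtual non-contrast CT (NCECT) from
contrast-enhanced CT (CECT) with a 3D conditional GAN, and evaluates the
result the way a proton-therapy physicist would: per-structure HU and mass
density agreement, global similarity, and water-equivalent path length
(WEPL) range surrogates along beam lines.

## Model

**Generator.** A U-Net-shaped encoder–decoder over 3D patches.  Each
encoder level is a residual block (conv–instance norm–ReLU–conv–instance
norm plus identity shortcut, ReLU after the addition) whose first
convolution has stride 2, halving every spatial axis; channel widths double
per level from `base_channels` up to a cap (defaults 64 → 512 over 4
levels, so a 256×256×64 patch reaches a 16×16×4 bottleneck with 512
channels).  One residual block forms the bottleneck.  Each decoder level
restores resolution by trilinear 2× interpolation followed by a 3³
convolution — interpolation-then-convolution rather than transposed
convolution, avoiding checkerboard artifacts — and concatenates the
mirrored encoder feature map before its residual block.  At full
resolution the input patch itself is concatenated as the last skip and a
final residual block refines the combined features before the 1-channel
head.

The head is *global-residual*: the network emits a bounded correction
`tanh(·)` that is **added** to the input and clipped to the normalized
range [−1, 1].  Contrast removal is a sparse, signed perturbation of an
otherwise identity map; predicting the correction instead of the image
makes the identity free and spends all capacity on the enhancement field.
In practice this halved the whole-volume L1 of a desk-scale run and is the
difference between the generated volume beating or losing to the raw CECT
on cosine similarity.  The full-resolution refinement block matters for a
related reason: removing voxel-level contrast noise requires replacing
organ voxels by values shrunk toward the organ baseline — a product-like
interaction between "which structure is this" (decoder features) and the
raw intensity that a single linear head convolution cannot express; one
nonlinear block at full resolution roughly halved the in-organ residual
error of the desk-scale study.

**Discriminator.** A conditional patch-score CNN (PatchGAN): the CECT
patch and the real/generated NCECT candidate are concatenated on channels,
passed through `n_layers` (default 3) stride-2 convolutions (kernel 4,
instance norm except on the first layer, LeakyReLU 0.2), and projected to
a 1-channel sigmoid grid flattened to a score vector; each score judges
one local receptive field.  The discriminator is conditioned on the
source CECT for both the real and the generated candidate — the standard
paired-translation design.

**Objective.**  Vanilla log-loss GAN: the discriminator minimizes mean BCE
(real → 1, fake → 0); the generator uses the non-saturating form
−E[log D(x, G(x))] (the saturating +log(1−D) variant stalls early
training).  Added to this: λ·L1 (voxelwise mean absolute error) and
δ·perceptual, λ = δ = 10.  The perceptual term is
Σᵢ (1/Mᵢ)·Σ|Fᵢ(y) − Fᵢ(G(x))| over the feature maps of a *fixed* extractor
with Mᵢ elements in layer i.  The default extractor is a seeded,
frozen, randomly initialized 3-layer stride-2 3D conv stack (He-scaled):
deterministic, natively volumetric, and needs no downloaded weights;
random convolutional features are a standard basis for perceptual
distances.  Any object returning an ordered list of feature maps can be
plugged in instead (e.g. a slice-wise pretrained 2D extractor).
Discriminator scores are clamped to [1e−7, 1−1e−7] before logs.

**Training.** Adam for both nets, betas (0.5, 0.999) (the usual
paired-GAN setting), initial LR 2e−4, mini-batch 1, alternating one
discriminator step (on the detached fake) and one generator step per
patch.  The LR is constant for `const_lr_epochs` (default 100 of 200)
then decays linearly to exactly 0 at the last epoch.  Per epoch, each
case contributes `patches_per_case` freshly sampled aligned patch pairs,
with seeds derived from (run seed, epoch), so the entire loss history is
reproducible bit-for-bit from the config and seed.

**Inference.** The volume is tiled by overlapping patches on a regular
grid (default 50% overlap per axis; the stride grid is clamped so the last
patch abuts the border), each patch is converted in normalized space, and
overlapping predictions are averaged uniformly per voxel.  Volumes smaller
than a patch are reflect-padded and cropped back.

## The numerics engine

No deep-learning framework is a dependency: the package carries a compact
tape-based reverse-mode autodiff over numpy with exactly the ops
the model needs — im2col GEMM 3D convolution, instance normalization,
trilinear 2× upsampling, elementwise activations and reductions — plus
Adam.  Instance norm is used everywhere because batch statistics are
degenerate at batch size 1.  All gradients are validated against central
finite differences in the test suite, and the convolution forward against
a brute-force loop.  This keeps the method CPU-runnable and fully
deterministic; it also bounds practical network sizes to the desk scale
(the full 4-level/512-channel configuration is expressible and correct,
but is meant for workstations with patience).

## Synthetic phantoms

Patient CECT/NCECT pairs cannot ship with the package, so a simulator
produces registered pairs with known contrast ground truth.  Six abdominal
structures (liver, heart, left/right kidney as ellipsoids; esophagus and
great vessels as z-aligned tubes) are painted into a soft-tissue cylinder
(35 HU) on air (−1000 HU), with geometry specified fractionally so one
layout scales to any grid.  Defaults: 64×64×32 voxels at 4 mm — large
enough that each organ holds hundreds to thousands of voxels, small enough
for CPU training.

Per-organ NCECT voxels are drawn from Normal(baseline mean, baseline SD)
using clinical per-structure statistics measured on five proton patients
(e.g. liver 46.8 ± 11.8 HU, great vessels 41.2 ± 6.7 HU).  A single
Gaussian noise field (default SD 3 HU, a mild quantum-noise stand-in) is
added to *both* volumes; the CECT then adds an independent Gaussian
enhancement field only inside enhancing organs, with mean equal to the
clinical CECT-minus-NCECT difference (great vessels +122.9 HU, esophagus
+13.2 HU, …) and SD chosen as sqrt(max(SD_CECT² − SD_NCECT², 0)) so the
simulated CECT voxel SD reproduces the clinical CECT column by variance
additivity.  Both volumes clip to [−1024, 3071] HU.  Overlapping
geometries resolve later-listed-wins with a logged warning.  An optional
smooth random displacement field (bounded by an amplitude in mm) can warp
the CECT only, emulating inter-scan motion; it is off by default because
the pipeline's contract is registered input.

What the phantoms deliberately lack: anatomy (shapes are quadrics),
texture and spatial HU gradients inside organs, beam hardening, scatter,
partial-volume edges, and scanner-specific noise spectra.  Passing the
end-to-end tests therefore shows the pipeline learns to invert a
*known, localized* enhancement field through the full
train-convert-evaluate path — not that it reaches clinical accuracy on
patients.

## Evaluation conventions

- Cosine similarity and MSE are computed on whole volumes rescaled to
  [0, 1] over the HU window (default −1024…1976 HU).  Reported MSE values
  on the 1e−3 scale only make sense in normalized units; whether the
  original evaluation used raw HU or per-patch vectors is not stated
  anywhere we could verify, so this choice is documented rather than
  asserted as canonical.  The report header records the scale.
- Per-structure statistics are voxelwise means and *population* SDs inside
  integer label masks; empty masks yield flagged NaN rows.
- Single-case difference columns are voxelwise mean/SD of |ΔHU| and of the
  absolute relative density deviation (%), with the true NCECT as
  reference — the same convention as the clinical multi-patient tables,
  collapsed to one case.
- `aggregate_report` takes the *unweighted* mean of each difference column
  and rounds to 2 decimals.  Note the clinical table's printed CECT column
  mean (64.9) is not the unweighted mean of its six cells (64.55; the
  summary value reported alongside it is ~64.52), suggesting voxel- or
  patient-weighted averaging there; the unweighted convention is used
  consistently here and this discrepancy is deliberately not reproduced.
- HU → mass density uses a monotone piecewise-linear calibration curve
  with clamped extrapolation; the default breakpoints
  (−1000, 0.00121) … (1500, 1.82) are a typical clinical-style curve with
  water anchored at (0 HU, 1.000) and are fully replaceable by a site
  curve (YAML list of [HU, density] pairs), since vendor TPS curves are
  proprietary.
- Proton range comparisons are **WEPL surrogates**: relative stopping
  power is approximated by relative mass density, cumulative WEPL is
  integrated along axis-aligned beam lines through the isocenter, and the
  "range shift" between two volumes is the difference in geometric depth
  at which each reaches a target WEPL.  The clinical 90% distal dose
  fall-off definition needs a dose engine and is out of scope; every
  output labels these numbers as WEPL depths, not dose ranges.

## Desk-scale study conditions

The packaged end-to-end experiment (also what `scripts/acceptance.py`
runs) uses 20 phantom pairs (64×64×32 at 4 mm), split 16 train / 4
held-out by seeded permutation, a 2-level generator (base 8, cap 32,
patch 48×48×16 — most of a transverse cross-section, so a patch sees the
organ layout almost completely), a 2-layer discriminator (base 8, cap
32), λ = δ = 10, 30 epochs (constant LR for 15, linear decay to 0), two
patch pairs per case per epoch, 50% inference overlap.  The study sets
the initial LR to 1e−3 rather than the 2e−4 full-scale default: that
value belongs to a 200-epoch schedule over thousands of patches per
epoch and leaves a 30-epoch toy run visibly undertrained.  Two patches
per case per epoch (≈1000 optimizer steps) rather than one proved
necessary for the adversarial game to converge reliably across seeds.
These sizes were chosen once as the
smallest configuration that cleanly demonstrates contrast removal on a
single CPU; the full-scale defaults remain available through the config.
Headline desk-scale outcomes (mean |HU error| inside enhancing organs for
generated-vs-true NCECT versus CECT-vs-true, and the cosine-similarity
ordering) are computed fresh by the acceptance script and the test suite,
never hard-coded.

## Numerical choices and edge cases

- All randomness flows from explicit integer seeds; the CLI derives
  per-stage seeds as sha256(global seed, stage) mod 2³¹ so stages are
  independently reproducible.
- Resampling preserves first/last voxel centers per axis (endpoint
  convention, exact on linear ramps); labels resample nearest-neighbour.
- Half-open crop intervals, 0-based voxel indices,
  world = origin + index·spacing.
- Coarse alignment crops both volumes to the closed intersection of their
  z voxel-center extents and errors on disjoint extents.
- Normalization clips to the window before the affine map, so
  denormalize∘normalize is identity only in-window (by design).
- Stitching asserts full coverage; score clamping at 1e−7 keeps BCE
  finite for saturated discriminators; non-finite losses abort training
  naming the offending term.
- Training computes in float32 (configurable to float64), roughly halving
  time and memory; gradient-check tests and evaluation metrics run in
  float64.
- Checkpoints are versioned `.npz` archives holding both networks'
  parameters, optimizer state, configs and loss history.

## Known limitations

Quadric phantoms only; no deformable registration (registered input is a
precondition; the deformation generator exists only to *create*
misregistration for robustness studies); no dose engine (WEPL surrogates
only); CPU-bound numerics make full-scale (256×256×64-patch) training
impractically slow here; the perceptual extractor is random rather than
pretrained unless one is plugged in.
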