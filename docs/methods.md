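# Methods

## Model and training procedure

`pedistrip` trains a voxel-wise brain/background classifier `g_θ` without any
acquired training images. The training distribution is defined by a generative
model over whole-head label maps: per step, draw a label map, augment it
spatially, render intensities from it, corrupt the rendering, and derive the
supervision target from the same augmented labels. The network therefore sees
an unbounded stream of (image, target) pairs whose intensity statistics change
every step while their geometry stays anatomically structured. The intended
consequence is contrast invariance: no fixed mapping from intensity to class
exists in the training data, so the decision function must rely on shape and
spatial context.

Assumptions worth stating explicitly:

- the label maps cover the whole head, so every voxel belongs to some label
  (synthesis needs non-brain labels as much as brain ones);
- the target definition (brain-label union, closing, hole fill) is taken as
  ground truth; the model can be no better than this definition;
- image and target are derived from the *same* augmented label map, so spatial
  correspondence is exact by construction — the label map is warped with
  nearest-neighbor interpolation first and the image rendered afterwards,
  never the reverse.

## Spatial augmentation

The affine part samples translation, per-axis rotation, scale and shear
uniformly from configured ranges, composed about the grid center. The
nonlinear part is parameterized directly as a dense resampling displacement:
per-axis Gaussian offsets on a coarse control grid (spacing
`warp_control_spacing`, standard deviation `warp_sd`), upsampled trilinearly —
continuous, varying only at the control-spacing scale, and cheap enough to
draw fresh every step. Under the small, smooth deformations used here this is
equivalent in distribution to composing a forward warp after the affine; no
invertibility is claimed or needed, since both image and target are resampled
through the same map. Out-of-field voxels become background.

## Intensity model and corruptions

Each label receives one mean drawn uniformly from `intensity_mean_range`
(default 0–255); a single global standard deviation is drawn from
`intensity_sd_range` (default 1–15); voxel values are normal draws clamped at
zero. Corruptions apply in a fixed order — multiplicative `exp` of a smooth
random field (log-amplitude `bias_field_sd`, default 0.3), min–max
normalization to [0, 1] followed by exponentiation with `exp(N(0,
gamma_log_sd))`, zeroing of random edge slabs (≤ `crop_max_fraction` per
axis), block-mean downsampling with nearest re-upsampling, and Gaussian
blurring (`blur_sigma_range`, mm). Normalization is unconditional; each other
stage fires with its own probability. All random draws happen whether or not
a stage fires, so configurations with different probabilities remain
draw-aligned, and a single seed sequence per (config seed, step seed) is split
into fixed per-stage streams.

## Targets

The brain mask merges all role-`brain` labels (ventricles included) and
excludes the non-ventricular CSF label, then applies 10 dilations followed by
10 erosions with the 6-connected (face-neighbor) structuring element, then
fills enclosed 3D holes. The closing runs on a volume padded by the iteration
count so the result equals the unbounded-grid closing intersected with the
field of view; without padding, a dilation clipped at the volume edge would
corrupt the subsequent erosion. 26-connectivity is available via a parameter.

The signed distance transform is Euclidean, in world mm, negative inside.
Distances are referenced to the boundary *face* between voxel centers:
`|sdt| = EDT_to_opposite_phase_center − spacing/2`. Consequences: the
transform is exactly antisymmetric under mask complement, never zero, and
thresholding at zero reproduces the mask bit-exactly — which is also the
inference rule of the SDT model variant. Against an oracle measuring distance
to boundary voxel centers, values differ by at most half a voxel.

## Network

Standard 3D U-Net, channels-last numpy arrays: per level two 3×3×3
convolutions with leaky-ReLU (slope 0.2), 2× max pooling between encoder
levels, nearest-neighbor upsampling followed by a convolution on the decoder
path (chosen over transposed convolution to avoid checkerboard artifacts;
kernel 3³ by default, 1³ available where full-resolution decoder cost
matters), skip concatenation, and a final 1×1×1 projection to two softmax
channels (brain, background) or one linear channel (predicted SDT, mm).
Channel width doubles per level from `base_channels`, capped at 256. The
documented full-scale preset is 7 levels, base 16; the desk-scale study uses
3 levels, base 8 (see below).

Three choices keep batch-1 optimization stable, and all were load-bearing in
development:

- per-channel instance normalization after every trunk convolution
  (`norm="instance"`, the default; `"none"` restores the plain conv trunk).
  Without it, activation scales drift multiplicatively through the nine-conv
  trunk, the logits explode, the softmax saturates, and the overlap loss —
  whose gradient vanishes at saturation — silently dies; runs then collapse
  to empty or all-head predictions depending on the seed.
- He initialization everywhere except the final projection, which starts at
  zero so the initial prediction is neutral (probability ½ everywhere).
- a smooth logit bound in softmax mode: logits pass through `B·tanh(z/B)`
  (`logit_bound`, default B = 10), capping them where float32 softmax would
  round probabilities to exact 0/1.

Forward and backward passes are explicit: convolutions are computed as 27
shifted BLAS matmuls (faster in practice than materializing the im2col patch
matrix), and the input gradient of a same-padded correlation is again a
same-padded correlation with spatially flipped, channel-transposed kernels.
Gradient correctness is verified in the tests by directional finite
differences through the whole network.

## Losses and optimization

Soft Dice is computed per channel, `D_c = (2Σ y_c p_c + ε) / (Σ y_c² +
Σ p_c² + ε)` with `ε = 10⁻⁶`, and the loss is `−(D_brain + D_background)/2`,
ranging over [−1, 0]. The SDT loss is `Σ w (d − d̂)² / Σ w` with `w = 1`
inside the band `|d| ≤ h` and `w = b` outside; `usdt` mode fixes `w = 1`
("unweighted" is read as uniform weights — `b` is a factor, not a length, so
the literal value quoted for the unweighted variant is interpreted as "no
down-weighting"; the literal `b = 0` remains expressible via parameters).

Optimization is Adam at batch size 1, with a global gradient-norm clip
(default 1.0) against the occasional extreme synthesis draw, an optional
linear warmup and cosine decay of the learning rate across the step budget,
and two optional recovery/selection mechanisms: restart-on-stagnation
(reinitialize when validation has not improved for `restart_patience`
validations while still above `restart_val_floor` — a failed-basin detector,
off by default) and tail weight averaging (average parameters over the final
fraction of the schedule; the averaged model replaces the best checkpoint
only if it validates better). Validation — mean (1 − Dice) of thresholded
predictions on held-out image/mask pairs, regardless of the training loss,
so loss variants are comparable — runs every `validation_interval` steps;
training stops after `plateau_patience` validations without improvement
beyond `plateau_min_delta`, returning the best-validation parameters.
Full-scale defaults: learning rate 1e-4, patience 5, min-delta 1e-4.

## Phantoms: what they emulate and what they don't

The phantom generator provides seeded, head-like label maps: a jittered
superellipsoid brain subdivided into white matter, cortical gray, deep gray,
ventricles, cerebellum and brainstem, wrapped in extracerebral CSF, skull and
scalp shells of exact metric thickness (built by Euclidean dilation), in
background. The low-frequency radial jitter makes the brain non-convex so the
closing stage has gaps to bridge. `make_phantom_image` renders acquired-like
scans with fixed per-label means; the T2-like table inverts the gray/white
ordering and brightens fluid, mirroring the contrast flip of early
development.

Phantoms do not emulate: real neuroanatomy (gyrification, partial volume,
thin CSF channels), motion or ghosting artifacts, inter-subject population
variability beyond seed jitter, or shoulders/chest in the field of view.
Passing desk-scale tests therefore demonstrates that the pipeline and
optimization behave correctly and that the synthesis strategy trains a
shape-based segmenter — not clinical-grade accuracy on real pediatric MRI,
which requires full-scale label maps and training budgets.

## Desk-scale study conditions

The reference experiment (`pedistrip.desk`, also run by
`scripts/acceptance.py`) uses 48³ grids at 1 mm, 8 training phantoms, 3
validation phantoms (6 images at both contrasts, close to the seven real
validation scans of the full-scale setup) and 2 held-out phantoms, rendered
with noise σ = 4; a 3-level base-8 U-Net with 1³ post-upsampling convs,
Dice loss, Adam 1e-3 with 50-step warmup and cosine decay, gradient clip 1,
600 steps, validation every 20. At this budget the whole run is pre-plateau,
so stopping is left to the step cap. The `SynthConfig.desk_scale` preset
shrinks metric augmentation ranges with the field of view (translation
±5.6 mm, warp control 6 mm with σ 2.25 mm, scale ≤ 1.1 and downsampling
factors {1, 2} — the phantom head fills ~90% of the field of view, and
factor 4 would leave ~4 voxels across a brain) and roughly halves corruption
probabilities: a few hundred batch-1 steps cannot average over rare extreme
corruptions the way a full-scale run can. Intensity randomization, the core
of the method, is unchanged. Typical behavior: ~94% validation-loss
reduction and held-out Dice ≈ 0.93–0.94 within the step budget.

## Numerical choices and degenerate inputs

- GMM label preparation: intensities outside the brain mask are fit with a
  full-covariance 1D Gaussian mixture (k-means++ initialization, seeded,
  variance floor 1e-6); components are relabeled by ascending mean so ids are
  reproducible, and hard assignments break ties toward the lower component
  index. The fit uses all non-brain voxels including background zeros.
- Non-uniformity correction divides by `exp` of a low-order 3D polynomial fit
  to log-intensity over nonzero voxels (zeros preserved exactly, mean
  preserved by rescaling). A low order is essential: quadratic and higher
  fits start absorbing smooth anatomy, so order 1–2 is the useful range and
  the estimate is a trend correction, not an N4 replacement.
- Conforming resamples intensities trilinearly and label maps/masks with
  nearest-neighbor (linear interpolation of integer labels is ill-defined),
  onto a left-inferior-anterior grid centered on the input volume's world
  center.
- Hausdorff distances use boundary voxel centers (boundary = mask voxel with
  a background face-neighbor) in world mm; both the classical maximum and the
  95th-percentile variant (max of the two directed percentiles) are reported.
- Dice of two empty masks is defined as 1; Hausdorff of an empty mask is an
  error.
- Degenerate inputs raise typed errors: all-zero images (bias correction),
  all-fore/background masks (SDT), empty weight bands (`b = 0` with no voxel
  within `h`), label maps without brain labels, grids not divisible at some
  U-Net level (the error names the level).

## Known limitations

- The numpy implementation is single-threaded BLAS-bound; a full-scale 256³
  seven-level training run is supported by the code but impractically slow
  compared to GPU frameworks.
- Cohort error maps are computed on the shared conformed grid; no nonlinear
  mid-space registration is performed, so they measure co-located error only
  up to affine alignment of the cohort.
- The `--no-csf` CLI flag is accepted for interface parity and is a no-op:
  CSF exclusion is already baked into the target definition.
- Checkpoints store raw float32 parameters; there is no quantization or
  format versioning beyond the embedded config.
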