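# Methods

`synthreg` implements a strategy for learning deformable, diffeomorphic
image registration without acquired images: label maps and images are
synthesized from noise at every training iteration, and the network is
optimized with a label-overlap loss that never sees intensities. This note
records the model, its assumptions, the parameters that matter, and the
numerical and design choices behind the implementation.

## Registration model

Given a moving image `m` and a fixed image `f` (affinely pre-aligned,
scalar, unit voxel spacing), a convolutional network `h_θ(m, f)` predicts a
stationary velocity field (SVF) `v` at half resolution. Integrating `v` for
unit time yields a topology-preserving deformation `φ = Id + u`; we
integrate by scaling and squaring: `u₀ = v / 2^S`, then `u ← u ∘ (Id + u)`
composed `S` times (default `S = 5` squarings). The half-resolution
displacement is linearly upsampled to the full grid with its values doubled,
converting half-grid to full-grid voxel units. Displacements are stored in
voxels with vector components on a trailing axis; `u(k)` tells where output
voxel `k` samples the input (pull-back warping), and out-of-grid samples
take the fill value 0 rather than edge clamping.

The training objective is

    L = L_dis(s_m ∘ φ, s_f) + λ · L_reg(u),

where `L_dis` is the soft Dice loss over one-hot label channels,

    L_dis = -(2/J) Σ_j |warp(s_m^j, u) ⊙ s_f^j| / (|warp(s_m^j, u) ⊕ s_f^j| + ε),

with `⊙`/`⊕` voxelwise multiplication/addition, `ε = 1e-5` guarding labels
absent from both maps, and one-hot channels warped with *linear*
interpolation so the loss is differentiable in `u`. Because `L_dis` is a
function of label geometry only, it is invariant under any intensity
transform of the images — the formal statement of contrast agnosticism.
`L_reg = ½·mean‖∇u‖²` uses forward differences with edge replication and
*mean* (not sum) aggregation over axes, components and voxels, making `λ`
resolution independent. Default `λ = 1`.

## Generative model

**Label maps.** For `J` labels (default 26), `J` smooth noise images are
drawn by sampling standard-normal voxels on a grid reduced by factor
`r_p = 1:32` (each dimension multiplied by `r` and rounded up) and linearly
upsampled. Each noise image is warped by a diffeomorphism integrated from a
random SVF whose standard deviation is drawn uniformly from `[0, b_p]`
(`b_p = 100` voxels), and each voxel takes the label of the largest warped
noise image. Argmax ties break to the lowest label index (a deterministic
choice for an essentially measure-zero event); every voxel receives a label,
and no background label is emitted unless requested.

**Training pairs.** In `shapes` mode one synthetic map is deformed twice by
independent SVFs combined additively across resolutions
`r_v ∈ {1:8, 1:16, 1:32}` with per-resolution SDs drawn from `[0, b_v]`
(`b_v = 3`), so both maps share one topology and an exact correspondence
exists. In `anatomy` mode two distinct maps from a user pool are each
deformed with a single-resolution SVF (`r_v = 1:16`), capturing
inter-subject variability instead.

**Velocity units.** All SVF magnitudes are expressed in full-resolution
voxel units: fields sampled on a coarse grid are upsampled *without* value
rescaling, so `b_p` and `b_v` bound the displacement rate on the full grid
regardless of the sampling resolution. (Value-scaled upsampling is the
convention for converting a displacement between grids, and is used when
the network's half-resolution integral is upsampled to the full warp.)

**Images.** From each label map, an image is rendered by a fixed chain:
(1) per-label Gaussian intensities with `μ_j ~ U(25, 225)`,
`σ_j ~ U(5, 25)`; (2) separable anisotropic Gaussian blur with per-axis SD
`~ U(0, b_K)`, `b_K = 1` voxel (kernels truncated at 3 SD, unit sum,
reflect boundary so edges are not darkened); (3) a multiplicative bias
field, `exp` of a smooth zero-mean field sampled at `r_B = 1:40` with SD
`~ U(0, 0.3)`; (4) min-max normalization to `[0, 1]` followed by global
gamma augmentation `m̃^exp(γ)`, `γ ~ N(0, 0.25²)`. A constant image
normalizes to zeros rather than dividing by zero. The two images of a pair
draw all contrast parameters independently, which decorrelates appearance
while preserving geometry. A smoothed random lookup table (256 entries
`~ U(0, 255)`, 1D Gaussian smoothing with SD `σ_L = 64`, linear
interpolation between entries) provides contrast augmentation of acquired
images for the hybrid training mode.

## Network and optimization

The U-Net encoder has 4 blocks (stride-2 convolution, `n` filters,
LeakyReLU 0.2), halving resolution each; the decoder has 3 blocks (stride-1
convolution + LeakyReLU, nearest-neighbour 2× upsampling, channel
concatenation with the matching encoder output), followed by 3 stride-1
convolutions at half resolution and a final convolution with one filter per
spatial dimension emitting the SVF. All kernels are 3 per axis; default
width `n = 256` (reduced for probe/desk experiments). The final layer is
zero-initialized so an untrained network predicts the identity warp — a
standard stabilization for SVF models; the remaining layers use He-normal
initialization. Inputs must be divisible by 2⁴.

Training uses Adam with batch size one and learning rate 1e-4, reduced once
to 1e-5 on divergence (non-finite loss, or the median loss over the last
500 steps exceeding the previous 500-step median by more than 0.2).
Validation computes hard Dice on 10 fixed held-out synthetic pairs. One
global seed fans out to independent streams for initialization, pool
generation, training and validation, so runs replay bit-exactly.

The network, spatial transformer and losses run on a compact reverse-mode
autodiff engine over numpy arrays written for this package; every operator
(convolution, warp, integration, resizing, penalties) has a hand-written
vector-Jacobian product covered by finite-difference checks in the test
suite.

**Supervised variants.** When both maps of a pair derive from one source
map the net warp is known. Composing the inverse of one sampled warp with
the other has no exact closed-form SVF, so supervised pairs are generated
with the moving map *undeformed*: `s_f = s_m ∘ (Id + ∫v)` for a sampled
`v`, making the sampled field exactly the regression target. `sup_svf`
compares at half resolution (values halved to half-grid units), `sup_def`
at full resolution, both with mean squared error.

**Hybrid mode.** Network inputs are remapped through independent smoothed
random lookup tables while the loss sees the un-augmented pair. The
similarity term is pluggable: soft Dice on the pool's label maps by
default, with an MSE image similarity provided; correlation-based
similarities are hooks only and not validated here.

## Desk-scale study configuration

The reduced configuration used by the tests and the acceptance script is
2D: a 64² grid, width `n = 16`, `J = 8` labels, 2000 iterations, with all
generator magnitudes and ratios kept at their reference values. A 64² run
takes roughly 40–50 ms per iteration on one CPU core, so the full study
completes in a few minutes.

What the desk scale does and does not show: the synthetic 2D study
exercises every component end to end — generation, differentiable warping,
the loss, optimization, evaluation — and the correctness suites (closed
forms, oracles, gradient checks) pin the numerics. It does *not* reproduce
the reference 3D accuracy: learning contrast-*invariant* features with
batch-size-one gradients is a slow warm-up. Controls isolate this cleanly:
a single fixed pair is registered almost perfectly within 50 iterations,
and disabling contrast randomization (rendering both images with one fixed
contrast) yields steady held-out Dice gains within 1500 iterations, whereas
under full contrast randomization thousands of iterations leave the model
near the identity — consistent with the reference schedule of 4×10⁵
iterations at width 256. The 2000-iteration Dice-gain check in the
acceptance suite documents this honestly rather than relaxing the
conditions. The 2D generator also does not emulate several properties of
acquired MRI — partial-volume mixtures beyond Gaussian blur, noise
correlations, k-space artifacts, anatomy-specific shape priors — so passing
tests certify the algorithmic machinery, not clinical performance.

## Evaluation metrics

Hard Dice is `2|A∩B|/(|A|+|B|)` per label (1 if both supports are empty, 0
if exactly one is). Mean symmetric surface distance extracts boundary
voxels by face-connected erosion (volume-edge voxels count as boundary),
computes exact Euclidean distances via a distance transform, and averages
the two directed mean nearest-boundary distances; with unit voxels the
value is identical in voxels and millimetres at 1 mm isotropic resolution.
Folding is the fraction of voxels with `det(J_φ) ≤ 0`, with the Jacobian by
central differences in the interior and one-sided differences at
boundaries. Bilateral-structure averaging is available as an optional
label-pairing table rather than hard-coded anatomy.

The contrast-invariance probe re-renders one geometry under several
contrasts against a constant fixed image, extracts a named layer's output
per pair, computes the RMS difference to the first pair over space per
feature channel, normalizes by the reference channel's spatial RMS (the
normalizer is a package choice; alternatives rescale but do not reorder
layers), and averages over contrasts and channels. The raw-input comparator
is the re-contrasted moving image itself under the same statistic.

## Numerical choices and edge cases

- Linear interpolation everywhere (warping, resizing, LUT); resizing maps
  grid endpoints to endpoints.
- Out-of-grid warping blends toward the fill value within the last voxel.
  At extreme velocity magnitudes (e.g. the shape generator's `b_p = 100`
  on small grids) zero-fill during squaring can create apparent folding
  near boundaries; diffeomorphism-by-construction statements apply to the
  pair-deformation magnitudes (`b_v = 3`), where sampled warps essentially
  never fold.
- The per-label fraction distribution of the shape generator is strongly
  right-skewed, so channel exchangeability is tested with omnibus
  (ANOVA/Kruskal–Wallis) statistics rather than per-label z-scores, which
  are miscalibrated at 50 samples under skew.
- 2D volumes are stored as NIfTI with a singleton third axis; vector fields
  carry components on a trailing dimension; label files must be
  integer-typed on disk (no silent casts).
- Checkpoints round-trip parameters bit-exactly.

## Known limitations

- CPU-only; paper-scale 3D training (width 256, 4×10⁵ iterations) is
  configurable but computationally out of reach of this engine.
- Desk-scale training does not reach contrast-invariant registration
  accuracy (see above); the supervised and hybrid modes are exercised for
  correctness, not accuracy.
- No affine pre-registration, B-spline/affine transform models, physical
  (mm) spacing, or MR signal-equation simulation.
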