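# Methods

This note records the models implemented in `spillsmooth`, the defaults
and why they were chosen, and what the synthetic benchmark does and does
not show about real data.

## GZ normalization

For an image with pixel values `x_j`, pixel count `n`, mean `X̄` and
population standard deviation `S = sqrt(Σx²/n − X̄²)`, the standardized
local Getis-Ord G\* at pixel `i` with binary neighbourhood weights is

    GZ_i = (Σ_{j∈N(i)} x_j − X̄·W_i) / ( S · sqrt((n·W_i − W_i²)/(n−1)) )

where `N(i)` is the set of in-image neighbours and `W_i = |N(i)|`.

Choices that matter:

* **Neighbourhood.** All integer offsets with Euclidean norm strictly
  below `distance_threshold` (default 1.5 → the 3×3 queen window). The
  focal pixel is included by default (`include_self=True`). Self-inclusion
  is the conventional G\* form and is what makes GZ a positive affine
  transform of the 3×3 box *sum* wherever `W_i` is constant — hence
  per-cell mean aggregation of GZ and of a 3×3 box blur rank cells
  identically on border-free images. `include_self=False` is available
  for sensitivity checks.
* **Borders.** Out-of-image neighbours are dropped (`W_i` shrinks); no
  padding, since padding would inject fabricated intensity. The GZ/box-blur
  equivalence therefore holds only away from borders.
* **Degenerate input.** A constant image has `S = 0`; GZ is defined as
  the all-zero field (with a warning and a `degenerate` flag) — "no
  spatial structure" is the correct limit for a normalization layer. A
  single-pixel image is an error.
* **Invariance.** `GZ(c·x + a) = GZ(x)` for `c > 0` holds algebraically;
  in floating point the agreement is at the 1e-9 level. This per-image
  affine invariance is the mechanism of the batch correction: each
  image/ROI is standardized onto a common scale.

Under spatial randomness (i.i.d. pixels) the interior GZ field has mean
≈ 0 and sd ≈ 1, which the suite checks on 256×256 uniform noise.

## Blur baselines

`box_blur(k)` is the mean over the k×k window, renormalized over
in-image pixels at borders. `gaussian_blur(k, sigma)` is a separable
Gaussian truncated to k×k and renormalized to sum 1; when `sigma` is not
given it defaults to `0.3·((k−1)/2 − 1) + 0.8`, stated explicitly so any
reimplementation is bit-comparable.

## SCI spillover correction

For each cell, the image/mask pair is split into an outside part
(mask `AM = 1` off the cell, intensity `AI` zeroed on the cell) and an
inside part (`BM`, `BI` complementary). Two influence fields are then
estimated and the correction `A − B` (default) or `(A+B)/2`
(`correction_mode="mean"`) is subtracted from the cell's boundary-ring
pixels (mask minus its per-cell 3×3 erosion) before mean aggregation.
Optionally the image is GZ-normalized first (`use_gz`). Non-boundary
pixels are never modified; with `clamp_nonnegative` (default) corrected
boundary pixels are floored at 0.

* **SCI1**: `A = G₅(AI)/G₅(AM)`, `B = G₉(BI)/G₉(BM)` — mask-weighted
  Gaussian means of the outside and inside intensity. The ratio form
  makes the fields exact local weighted averages, so on a locally
  constant image `A = B` and the correction vanishes.
* **SCI2**: a bank of 8 Gabor-like kernels (size 7, σ = 3, λ = 10,
  γ = 5, ψ = π/2, θ_k = k·π/4) is convolved with `AI`, `BI` and `BM`.
  With ψ = π/2 every kernel is exactly odd along its oriented axis:
  kernels sum to zero and kernel(θ+π) = −kernel(θ). Per pixel, the
  orientation responding most strongly to the inside mask
  (argmax over the `BM` responses) selects the inside-contribution
  channel read from the `BI` responses — effectively reading the
  intensity perpendicular to the local mask edge — while `A` is the
  per-pixel maximum response of the outside intensity. Both fields are
  floored at 0, as they model nonnegative influences.

  *Why select on the inside-mask responses?* Since `BM = 1 − AM` and the
  kernels are odd, the outside- and inside-mask response stacks are
  pixelwise negations of each other away from image borders. Selecting
  the channel by the *outside*-mask argmax would therefore pick the most
  negative inside response, making `B ≡ 0` after flooring and leaving a
  spurious positive correction `A` even on a perfectly flat image.
  Selecting on the inside-mask argmax makes `A = B` exactly on constant
  intensity, so the correction is neutral where there is nothing to
  correct. The test suite pins this neutrality at 1e-5 relative.
* **Ambiguity rule.** If the argmax over bank responses is tied (within
  1e-9), the channel perpendicular to the argmin (offset by 4, i.e.
  θ+π) is used; argmin ties break toward the smallest index. This keeps
  the procedure fully deterministic, including on structureless windows.
* **Windowing.** Fields are computed per cell on its bounding box padded
  by the kernel radius; every cell pixel then has its full kernel
  support inside the window, so the windowed fields equal the
  whole-image computation exactly (tested at 1e-9). Cells whose padded
  window crosses the image border are flagged (`border_cell`): their
  fields are zero-padding approximations.
* **Correction combination.** Both the difference (`A − B`) and the mean
  (`(A+B)/2`) combination are implemented; the difference is the
  default. The two disagree on purpose — they encode two plausible
  readings of how the influences should be combined — and results
  should state which was used.

## RATI

Per iteration, every cell is transformed by an independent random affine
draw — scale U(0.8, 1.2) (isotropic), translation U(−1, 1) px per axis,
shear U(−0.1, 0.1), rotation U(−15°, 15°) — about its centroid, in the
order translate(centroid) ∘ rotate ∘ shear ∘ scale ∘ translate(−centroid)
plus the drawn translation. Cells are stamped in a fresh canvas in random
visit order, later cells overwriting earlier ones; pixels that were
foreground originally but became background are then closed per cell
(3×3 closing claiming only still-background pixels, same order). The
footprint transform is a nearest-neighbour inverse warp, so identity
parameters reproduce the input mask bit-exactly and RATI degenerates to
plain mean aggregation. Default 25 iterations (gains appear from ~10;
more buys a little extra stability); the median over iterations is the
reported intensity and the iteration sd is kept as a diagnostic. Cells
absent from every resampled mask fall back to the original-mask mean and
are flagged.

## Segmentation perturbations

* **Single-cell spillover simulation**: for sampled cells, a random
  operation (dilate/erode), quadrant (relative to the cell centroid, in
  image axes) and range (1 or 2 px) are drawn. Dilation overwrites
  neighbouring labels — deliberately, because claiming only free space
  would create no spillover in dense tissue. Records of the modified
  cells are returned so evaluation can be restricted to them.
* **Undersegmentation**: per-cell erosion by 1 or 2 px (3×3 element);
  cells eroded to nothing vanish. **Oversegmentation**: per-cell dilation
  claiming only background, so in dense tissue it only acts at the image
  border. The two intentionally differ in their overwrite rule.

## Synthetic tissue generator

The generator emulates the study conditions: small, densely packed cells
with a median 2D footprint of 31 μm² (median equivalent-circle diameter
~6 μm), two marker populations per channel, and acquisition at 1 μm
pixels from a finer simulation grid.

* **Geometry.** One seed point per target cell on a jittered grid
  (spacing √31 μm, jitter ±0.35 spacing), turned into a space-filling
  power diagram (label = argmin of squared distance minus a per-cell
  weight drawn U(0, (0.45·spacing)²)). Power cells are convex, hence
  connected, and the weight spread gives realistic size dispersion while
  the mean area stays pinned at field-area / n-cells, which keeps the
  median at the target (~1% accuracy at the default 0.25 μm grid).
  Background exists nowhere in the interior. The assignment uses the 12
  Euclidean-nearest seeds per pixel, which is exact for these mild
  weights.
* **z-correlation.** Seed points drift by a Gaussian random walk of
  1 μm sd per slice, so a cell traverses roughly a third of its diameter
  over a 4-slice stack. This is the mechanism that couples tissue depth
  to lateral mixing after projection: the acquisition mask is the
  per-pixel z-mode of the labels (ties to the smallest label) while the
  intensity is the z-and-block mean, so columns visited by several cells
  mix their signals. With a much smaller drift, z-depth would have no
  effect on marker separability.
* **Channels.** Class per cell ~ Bernoulli(p_positive = 0.5),
  independent across channels. Mean expression per cell is
  `exp(t)`, `t ~ Normal(μ_class, σ)` truncated to `[0, ∞)` (bounds are a
  declared choice; they guarantee positive pre-exp values). The two
  stock channels are `ch0` (μ⁻ = 0.5, μ⁺ = 1.3, σ = 0.3 — noisy, low
  contrast) and `ch5` (deterministic 0/100 — noiseless, high contrast).
  Localization is whole-cell or membrane (boundary ring only).
* **Noise.** A constant offset (default 0.1) plus smooth gradient noise —
  a coarse Gaussian random field upsampled with cubic interpolation,
  min-max scaled to [0, 1], amplitude 0.2, correlation length 20 px.
  Amplitude, length and offset are defaults declared here, not inferred
  from any source.
* **Resolution.** Masks downsample by nearest neighbour in xy (the
  sample at the floor of each block centre — deterministic) and the mode
  along z; intensities downsample by block mean (chosen over nearest
  neighbour because the mean-intensity image is downsampled *before*
  Poisson sampling, and a block mean preserves expected counts exactly).
  Counts are per-pixel Poisson draws from the downsampled mean. The
  noise-free variant skips offset, noise and the Poisson step.
* **Determinism.** One seed drives four spawned generator streams
  (geometry, truth, noise, counts); identical configs give bit-identical
  outputs.

### What the simulator does and does not capture

It reproduces dense packing, size dispersion, partial-volume mixing in
xy and z, membrane-localized markers, shot noise and background drift.
It does not model nucleus/cytoplasm compartments, cell-type spatial
autocorrelation (classes are spatially random, which is the worst case
for smoothing — any blur hurts when neighbours are uncorrelated),
antibody aggregates/hot pixels, isotope-impurity spillover between
channels, or real segmentation-algorithm error modes. Passing trends on
this benchmark therefore bound what resolution and mask error alone do
to mean aggregation; they do not certify performance on real tissue.

## Evaluation

* **AUROC** by rank-based pair counting; ties get half credit by
  default (the rank convention), with a strict indicator variant
  (`s⁺ > s⁻` only) available. Exactness against a brute-force
  double loop is part of the suite.
* **max-F1**: exhaustive scan over midpoints between consecutive
  distinct scores plus ±∞, classifying positive at `s ≥ t`; F1 ties
  resolve to the lowest threshold, and F1 with TP = 0 is 0.
* **Population distance**: |mean⁺ − mean⁻|, optionally over the pooled
  (ddof = 1) sd.
* **Inverse Simpson index**: per cell, the effective number of groups
  among its k nearest neighbours (Euclidean, self excluded), averaged;
  k defaults to 100. This is a deliberately simple batch-mixing score,
  not a reimplementation of any specific external tool.
* **Sweeps**: the resolution sweep simulates the noise-free
  deterministic channel over a grid of xy factors, z depths and
  localizations and reports mean AUROC across seeds; the method
  comparison scores every aggregation strategy on identical inputs
  against the `mean` baseline.

## Problem sizes and numerical conventions

The test suite and sweep defaults use 60–120 μm fields (roughly 100–1300
cells) and 10 seeds per condition — the package's chosen desk-scale
study size; the calibration script uses the full 200×200 μm default
field (~1300 cells). Coordinates are 0-based (row, col), origin top-left;
pixels are unit squares; kernel sizes are odd side lengths centred on
the pixel; cell ids are stable through every operation (nothing
renumbers labels); the default pixel size is 1 μm when metadata is
absent. Structured tie-breaks (smallest label for the z-mode, smallest
k for Gabor argmin ties, ascending-id visit order for oversegmentation)
exist purely to keep every operation deterministic.

## Known limitations

* SCI fields at image borders are zero-padding approximations; affected
  cells are flagged rather than corrected differently.
* RATI's randomness means two seeds give (slightly) different values;
  the median over ≥ 25 iterations keeps the spread small but not zero.
* The ISI here uses a plain Euclidean kNN graph on whatever features are
  given; it is sensitive to feature scaling.
* The generator's cells are convex; real cells are not, and concave
  geometry would change boundary-ring statistics somewhat.
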