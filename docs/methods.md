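# Methods

This note documents the models and procedures implemented in `uatransnet`,
the assumptions behind them, the defaults that matter, and the numerical
choices made where the design was genuinely open.

## Phantom generator

The generator emulates the salient prior of tumor MRI slices: a lesion
region that is *brighter* than surrounding tissue, roughly elliptical,
variable in size and position, with blurred edges and acquisition noise.
A phantom is built as the union of rotated ellipses (semi-axes drawn
uniformly from `semi_axis_range`, rotation uniform in [0, π), centers
placed so the ellipse fits the frame), rendered as a two-level intensity
field (`fg_intensity`/`bg_intensity`, defaults 0.75/0.25 on the unit
intensity scale), Gaussian-blurred (`edge_blur_sigma`, default 1 px) and
corrupted by additive Gaussian noise (`noise_sd`, default 0.05), then
clipped to [0, 1].  Defaults — 64×64 frames, one tumor of 6–14 px
semi-axes — were chosen once as a plausible desk-scale rendering of a
lesion slice; no quantitative description of the original clinical images
is available, so these values are this package's own.

What the phantoms do **not** model: MRI physics (bias fields, Rician
noise), anatomy and texture inside or outside the lesion, multi-slice
structure, and lesions *darker* than their surroundings.  Results on
phantoms therefore demonstrate that the implementation is correct and that
the pipeline works when the brightness prior holds; they do not predict
clinical segmentation accuracy.

Determinism: a `PhantomSpec` carries its own seed and equal spec+seed
yields bit-identical output; datasets derive per-item seeds from a
`SeedSequence`, so item `i` is independent of the dataset size.

## Classical suspected-region pipeline

* **ROI detection** is a deliberately simple intensity-percentile bounding
  box (pixels above the 95th percentile, 2 px margin): plumbing standing in
  for a learned detector, adequate under the brightness prior, and it
  fails loudly (constant image → error) rather than guessing.
* **Histogram adjustment** is two-tailed contrast clipping: the lowest and
  highest 5% of cumulative mass map to 0 and 1, interior rescaled linearly.
  The 5% figure is the documented convention of the method family; the
  operation is monotone (never reorders intensities).
* **Filtering** inside the ROI only: median (impulse noise), mean (false
  contours left by the median), then edge enhancement `I − λ·∇²(G_σ∗I)`
  with λ = 0.5 and σ = window/6.  The discrete 5-point Laplacian of a
  constant is exactly zero, so flat regions are untouched — a property the
  truncated Laplacian-of-Gaussian kernel does not have, which is why the
  smooth-then-Laplace form was chosen.  The window is
  `ceil(0.05·max(ROI height, width))` rounded up to odd, floored at 3.
* **Otsu size estimation** uses a 256-bin histogram over the observed
  intensity range, exhaustive scan, ties broken toward the lowest bin; the
  returned level is the chosen bin's upper edge so foreground means
  `value > level`.  The smaller/larger class pixel counts become the size
  band `[lower, upper]`, and the level seeds the growth threshold.  A
  near-constant ROI (Otsu undefined) falls back to the full-ROI band.
* **Seeded region growing** starts from the k = 5 brightest pixels in the
  central third of the ROI (ties row-major).  A frontier pixel of intensity
  `I` is admitted iff `I > θ` and `μ − I < θ`; μ is the running mean of
  the accepted region, updated after every admission — "the segmented
  region" is read as the region as it currently stands.  Growth is
  breadth-first with 4-connectivity by default and is confined to the ROI
  box.  After each pass, if the region is below the size band, θ drops by
  `theta_step` (default 0.05, i.e. 5% of the unit range) and growth
  continues *from the current region*, for at most `max_rounds` = 20
  rounds; exceeding the band or entering it stops the loop.

Numerical notes.  The two admission tests make the effective intensity
bound `max(θ, μ − θ)`: for θ ≥ μ/2 the bound is θ itself, so with frozen μ
the region is non-increasing in θ — the lever the adaptive loop relies on
(initial θ comes from the Otsu level, which sits above μ/2 for bright
lesions on dark ground).  Below μ/2 the second test dominates and the
monotonicity reverses; the adaptive loop is insensitive to this because it
keeps the already-grown region between rounds.  At θ = 0 the strict
inequality `μ − I < 0` admits only pixels brighter than the running mean,
so growth on a flat plateau stops at the seeds; this is the literal
reading of the two conditions and is covered by a regression test.

## Network

Residual blocks are three 3×3 convolutions, each followed by GroupNorm
(default 8 groups; group count must divide the width) and ReLU, plus an
additive shortcut (1×1 projection when widths differ).  GroupNorm rather
than BatchNorm keeps statistics independent of the (small) batch.
Downsampling is 2×2 max-pooling; channel widths double per scale from
`base_width`; upsampling is bilinear with aligned corners everywhere.
The loss is binary cross-entropy plus soft Dice — the Dice term directly
optimizes the reported overlap metric and is robust to the foreground/
background imbalance of small lesions.  Optimizer is Adam.  The learning
schedule is a 1e-3 baseline dropping to 1e-4 at epoch 50, cosine-annealed
across the run — at test scale (≤10 epochs) only the annealed 1e-3 phase
is ever reached.

Two presets: `TEST_SCALE` (depth 3, width 8, 64×64) for CPU-scale runs,
and `PAPER_SCALE` (depth 4, width 36, GroupNorm groups 4, 256×256) whose
parameter count lands at 17.0M (residual) / 18.8M (dense), near the
reference operating point of this architecture family.  Problem sizes in
the tests and the acceptance script (200 training phantoms at 64×64, six
epochs, 40 held-out) are the package's chosen desk-scale conditions; they
reach held-out DSC ≈ 0.98 because the phantom task is easy by design.

**Attention bottleneck.**  The fusion scalars α₁, α₂ start at 0, so a
model with the bottleneck is bit-identical to its attention-free twin at
initialization (backbone and attention parameters are drawn from separate
seed streams to guarantee this).  Design choices that the source
formulation leaves open, resolved here:

* The printed position-aggregation formula collapses to a constant
  (columns of `L` are normalized), so the aggregation runs over the
  full-channel map `U` — `out_j = Σ_i L_{i,j}·U_{:,i}` — restoring the
  channel count the fusion sum requires.
* Channel attention is single-head by default; an optional head count
  splits channels, each head attends with `d_k = c/heads`, and a final
  c×c embedding mixes the concatenation.
* Softmax axes: CAM normalizes over the key index of each query row
  (standard attention convention); `L` normalizes over the source
  position `i` for each target `j`.  Logits are max-shifted before
  exponentiation.
* The two GCAC compressions use independent 1×1 convolutions (`V` as
  queries over i, `W` as keys over j); `c₁ = max(1, c₀/8)`.
* The learned position encoding is a per-bottleneck `c×h×w` array added
  elementwise and shared by all heads, which ties a model to its
  configured input size.

**Skip fusion.**  The residual decoder stage transforms (encoder skip ⊕
upsampled previous decoder feature) through a residual block; the dense
decoder stage receives *all* previous decoder outputs (bottleneck
included) upsampled to its resolution plus the encoder skip, giving
d(d−1)/2 cross-stage reuses at depth d.  A cascade-fusion block
(upsample-all, concatenate, mix) is provided as a standalone component.
Where each scheme applies per stage is not prescribed by the source
architecture; here the whole decoder follows one scheme selected by
`skip_mode`.

## Mean-teacher stage

The classifier (residual blocks + max-pooling + global average pool +
fully connected sigmoid head) is trained with
`Loss = BCE + w·JS(student, teacher)`.  Choices:

* The consistency term is the Jensen–Shannon divergence with mixture
  `M = (P+Q)/2` — symmetric, bounded by ln 2, zero iff the distributions
  agree within clipping.  (A literal reading of the printed consistency
  formula contains a term that is identically zero; the JS form matches
  the stated intent of symmetrizing KL.)  Binary predictions are treated
  as two-point distributions (p, 1−p); probabilities are clipped at 1e-7.
* EMA decay α defaults to 0.99 (unstated in the source), with the usual
  warm-up `α_t = min(α, 1 − 1/(t+1))` so early teachers track the student
  instead of the random initialization.
* Consistency weight defaults to 1 with an optional linear ramp-up.
* Student and teacher see independently noised views of the unlabeled
  batch (additive Gaussian, σ = 0.05); no gradient flows into the teacher.
* The supervised loss uses ground-truth labels against the student, per
  the loss definition (the surrounding prose is ambiguous about the
  teacher's role in this term).

The effective/difficult partition thresholds the classifier's confidence
at 0.5 by default.  The published 39.4%/60.6% split of the clinical
dataset depends on that embargoed data and is not a reproducible target;
the tests instead verify that a constructed 40/60 phantom mix is
recovered to within 10 points.

## Evaluation

Zero-denominator metrics are reported as undefined (`None`), never 0.
Per-image (macro, mean ± sd) and pooled-count (micro) aggregates are both
reported; tables round to 3 decimals.  The stratified splitter uses
largest-remainder apportionment so the global train count is hit exactly
while every stratum stays within one case of the global fraction; the
286-case cohort with age strata 71/186/29 at train count 216 reproduces
the 75.52%/24.48% split.  Percent changes are computed, not transcribed:
TP 45→53 is +17.78% (printed elsewhere truncated to one decimal).

## Known limitations

* The autodiff engine is eager and single-threaded numpy; it is sized for
  the test-scale presets, and the 256×256 paper-scale preset, while
  functional, is slow to train on one CPU.
* Bilinear upsampling uses aligned corners only; pooling requires even
  spatial dimensions, so input sides must be divisible by 2^depth.
* The ROI detector assumes exactly the brightness prior the phantoms
  implement; low-contrast lesions (small grayscale difference) defeat both
  the detector and the region grower, as they do for any purely
  intensity-based method.
* `scale` augmentation re-rasterizes through zoom-and-crop and is not a
  pixel-exact group operation like the rotations/flips.
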