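# uatransnet

Segmentation of bright tumor lesions in MRI-like grayscale images, built
around a U-shaped encoder–decoder (UATransNet-style) with a **multilevel
guided self-aware attention bottleneck**, a **mean-teacher** dataset
optimization stage, and a classical **adaptive region-growing**
preprocessing pipeline.  Everything is exercisable on synthetic phantoms —
bright, roughly elliptical lesions on darker tissue with blurred edges and
additive noise — so no clinical data are required to run, test, or extend
the code.

It is aimed at researchers in medical image analysis who want a compact,
fully inspectable CPU implementation of these components: the network runs
on a small numpy reverse-mode autodiff engine that ships with the package
(`uatransnet.engine`), with no deep-learning framework dependency.

## The model

**Attention bottleneck (MGAM).** At the coarsest scale the encoder feature
`F ∈ R^{c×h×w}` (flattened to `c×n`, `n = h·w`) passes through two
attention components:

* *TSAC* — channel-level self-attention.  After adding a learned position
  encoding, channel-mixing projections give `Q, K, V`; the contextual
  attention map `CAM = softmax(Q·Kᵀ/√d_k)` is `c×c` (rows are probability
  vectors) and the output is `CAM·V`.
* *GCAC* — position-level attention.  Two 1×1 convolutions compress the map
  to `c₁ = c₀/8` channels giving `V, W`; the position attention map
  `L_{i,j} = softmax_i(V_i·W_j)` is `n×n` (columns sum to 1) and position
  `j` of the output aggregates `Σ_i L_{i,j}·U_{:,i}` over the full-channel
  map `U`.

The fused bottleneck output is `α₁·TSAC(F) + α₂·GCAC(F) + F`, with the
scalars `α` learnable and initialized to 0 — at initialization the network
is exactly its attention-free twin.  The decoder reassembles resolution
through either **residual** or **dense** multiscale skip fusion; blocks are
three 3×3 convolutions with GroupNorm and an additive shortcut.

**Mean-teacher dataset optimization.** A classifier is trained on a
partially labeled set with `Loss = BCE(labels, student) +
w·JS(student, teacher)` where the teacher's parameters are an exponential
moving average `θ′_t = α·θ′_{t−1} + (1−α)·θ_t` of the student's.  The
trained classifier partitions a dataset into *effective* and *difficult*
parts by confidence.

**Classical preprocessing.** ROI detection → two-tailed 5% histogram
clipping → median/mean/Laplacian filtering (window = 5% of the longer ROI
side, odd) → Otsu split of the ROI histogram for a size band `[lower,
upper]` and initial threshold θ → seeded region growing from the brightest
central pixels, admitting a neighbor of intensity `I` when `I > θ` and
`μ − I < θ` (μ = running region mean), lowering θ stepwise while the region
is below the size band.

**Metrics.** ACC, PRE, REC, IOU, DSC = 2|A∩B|/(|A|+|B|) and F1, computed
per image (macro mean ± sd) and on pooled pixel counts (micro), plus a
stratified cohort splitter with largest-remainder rounding.

## Worked example

```python
from uatransnet.phantom import PhantomSpec, generate_phantom
from uatransnet.preprocess import segment_suspected_region
from uatransnet.evaluation import dsc_from_masks

item = generate_phantom(PhantomSpec(seed=3, noise_sd=0.02))
mask, info = segment_suspected_region(item.image, return_info=True)
est = info["estimate"]
print(f"Otsu level (theta0): {est.otsu_level:.3f}")
print(f"size bounds (px)   : [{est.lower_px}, {est.upper_px}]")
print(f"grown region (px)  : {int(mask.sum())}  (truth: {int(item.mask.sum())})")
print(f"DSC vs ground truth: {dsc_from_masks(mask, item.mask):.3f}")
```

prints

```
Otsu level (theta0): 0.598
size bounds (px)   : [206, 234]
grown region (px)  : 234  (truth: 168)
DSC vs ground truth: 0.836
```

The Otsu split of the ROI histogram estimated the lesion between 206 and
234 pixels and provided the initial growth threshold 0.598; growth stopped
once the region entered that band, overshooting the 168-pixel truth on
this blurred phantom but still overlapping it at DSC 0.84.  Training the
small network preset instead of the classical pipeline reaches held-out
DSC ≈ 0.98 on the same phantom family (see below).

The same stages are available from a shell:

```bash
uatransnet generate -n 200 --seed 7 -o data/
uatransnet train --manifest data/manifest.csv -o run/
uatransnet eval --checkpoint run/checkpoint.npz --manifest data/manifest.csv -o report/
uatransnet segment --checkpoint run/checkpoint.npz data/img_00000.png -o mask.png
uatransnet preprocess data/img_00000.png -o pre/
uatransnet alpha-grid --checkpoint run/checkpoint.npz --manifest data/manifest.csv -o grid/
```

`rot90` in the augmentation ops is counter-clockwise; all knobs live in a
single YAML config (`--config`), echoed into every output directory.

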