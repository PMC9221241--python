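# Methods

## Model

The segmenter is a U-shaped encoder–decoder over single-channel 2D slices,
mapping an S×S image (S divisible by 2^depth, default depth 4, S = 512) to
per-pixel foreground probabilities in (0, 1).

**Main encoder.** Level *l* (resolution S/2^(l−1)) applies two 3×3
convolution blocks (conv → batch norm → ReLU) at width `channel_schedule[l−1]`,
then a squeeze-and-excitation (SE) block, exports the result as the level's
skip, and 2× max-pools. SE pools each channel to its spatial mean, passes
the vector through a bottleneck MLP (reduction 8) and rescales channels by
sigmoid gates — channel attention that suppresses redundant features.

**ASPP bottleneck.** On the deepest pooled features, parallel 3×3 atrous
convolution blocks at dilation rates {1, 6, 12, 18} (receptive field
2d+1 per axis at constant parameter cost) are concatenated and fused by a
learned 1×1 convolution block. No image-level pooling branch: it buys
little at 1/16 resolution and would inflate the parameter budget.

**Enhanced encoder** (full variant only). A parallel branch over the raw
input: a 3×3 convolution-block stem, then per level a stack of
depthwise-separable blocks (3×3 depthwise + 1×1 pointwise, each with BN +
ReLU), each level 2× max-pooled. It emits one feature map per level at
resolution S/2^l. The deepest map joins the ASPP output at the bottleneck;
the intermediate maps enter the matching decoder stages as secondary skip
connections. Stacked separable convolutions add depth and keep shallow
boundary detail at a small fraction of the dense-conv parameter cost
(k²C_in + C_inC_out versus k²C_inC_out).

**Decoder.** Stage *l* (deepest first) bilinearly upsamples 2×,
concatenates the main-encoder skip of level *l* and (full variant, l ≥ 2)
the enhanced map at that resolution, then applies two convolution blocks
at the level's width. A final 1×1 convolution (with bias) and a sigmoid
produce the probability map; masks are thresholded at 0.5.

Conventions: stride-1 "same" zero padding everywhere (only pooling and
upsampling change resolution); convolutions followed by BN carry no bias;
He-uniform initialisation from a seeded generator, so a (config, seed)
pair reproduces the graph bit-for-bit; BN eps 1e−5, running-stat momentum
0.9. Bilinear upsampling (not transposed convolution) keeps the decoder
parameter-free at the resolution change and avoids checkerboard artefacts.

## Losses

Over the flattened pixels of a batch (y ∈ {0,1}, p ∈ (0,1), N pixels):

* BCE, mean-reduced: −(1/N) Σ [y ln p + (1−y) ln(1−p)]; probabilities are
  clamped to [1e−7, 1−1e−7] before logs.
* Dice: 1 − (2Σyp + δ)/(Σy² + Σp² + δ), δ = 1e−15 by default (any value
  in [1e−15, 1e−13] changes the loss by < 1e−10 on non-empty masks); δ
  guards empty masks and gives all-background batches a gradient.
* Hybrid: sqrt(BCE² + Dice²), computed per batch. It inherits scale from
  whichever component is currently larger, balancing the imbalance
  robustness of Dice with the well-conditioned gradients of BCE.
* Focal (comparison baseline): −mean[α(1−p)^γ y ln p + (1−α)p^γ(1−y) ln(1−p)],
  defaults γ = 2, α = 0.25; reduces to α-weighted BCE at γ = 0.

Reduction choice (flattened batch pixels, mean-reduced BCE) keeps loss
magnitudes comparable across resolutions and batch sizes. Each loss ships
with its exact analytic gradient; the test suite verifies all of them, and
every network layer, against central finite differences (rel. tol. 1e−4
or better).

## Parameter-budget calibration

The published budgets are 7.0 M (full) and 3.8 M (lite) trainable
parameters, but no channel schedule is published. `calibrate_config`
freezes one: stage 1 keeps the geometric schedule (32, 64, 128, 256) and
scans the ASPP width until the lite count rounds to 3.8 M (result: 56);
stage 2 scans the enhanced-encoder base width and stack depth until the
full count rounds to 7.0 M (result: schedule (70, 140, 280, 560), 3
separable blocks per level). The counter tallies every trainable scalar
(conv/dense weights and biases, 2C per BN layer; running statistics are
not trainable). Frozen result:

| variant | parameters | millions |
|---|---|---|
| full | 7,008,469 | 7.0 |
| lite | 3,808,909 | 3.8 |

The 3.2 M full−lite gap cannot come from the separable convolutions alone
(they are cheap by construction); it is dominated by the widened decoder
concatenations, which forces the enhanced encoder to be wider than the
main one. This is the one place where the budget constraints, not the
prose description, fix the design.

## Training protocol

Adam (β₁ 0.9, β₂ 0.999, ε 1e−8), learning rate 1e−4, batch 16, up to 300
epochs with early stopping (patience 20) on validation DSC, restoring the
best weights — the full-scale protocol at 512×512. Optional online
augmentation per batch: rotation uniform in ±15°, elastic deformation
(Gaussian-smoothed displacement field, α 15 px, σ 3 px — chosen so a
1000-px blob changes area by < 20%), additive Gaussian noise (sd 10);
image and mask receive the identical geometric transform and masks are
re-binarised at 0.5.

A CPU profile (`TEST_SCALE_CONFIG` / `TEST_SCALE_TRAIN`) ships for
desk-scale work: 64×64 inputs, schedule (8, 16, 32, 64), ASPP width 32,
enhanced schedule (8, 16, 32, 64) with stack 1 (~359 k parameters),
learning rate 1e−3, ≤ 30 epochs. The higher learning rate matches the
smaller parameter count and image area; at this scale the smoke benchmark
(200 slices, 8:1:1 case split) trains in a few minutes on one CPU.

## Data handling

NIfTI volumes are read unresampled (nibabel), min–max rescaled per volume
to [0, 255], and cut along the third array axis into axial slices; masks
binarise at 0.5. Slices resize bilinearly (masks: nearest-neighbour, then
re-binarised, stratum recomputed). Splits are 8:1:1 by **case**, not by
slice, so no patient contributes to two partitions; the split is a seeded
deterministic partition. Noise-robustness evaluation corrupts the [0, 255]
image with i.i.d. N(0, σ²), σ = 40 by default, clipped to range.

Lesion-size stratification uses half-open intervals on the ground-truth
foreground count: lesion-free (0), small [1, 100), medium [100, 1000),
large [1000, ∞) — the count 100 is medium, 1000 is large. Per-slice
metrics are macro-averaged within strata (micro pooling would let large
lesions dominate exactly the per-size analysis the strata exist for);
empty/empty degenerate ratios score 1.0; lesion-free slices are counted
but excluded from metric rows.

## Synthetic data

Each slice is a randomly placed/rotated bright ellipse ("brain",
intensity ~175) with smooth Gaussian-filtered texture (sd 8) on a dark
background (~35). Lesions are grown by randomised frontier accretion
(Eden growth) inside the brain interior, giving irregular, connected,
rough-boundary blobs; the total lesion budget is sampled uniformly inside
the requested stratum interval and hit exactly. Lesion pixels are darkened
by an amount in (drop/2, drop], drop = 60, guaranteeing learnable contrast
while overlapping the texture variation. At 64×64 a large-stratum lesion
occupies a substantial brain fraction; below that the generator raises an
error rather than silently violating the stratum contract.

What passing on this benchmark shows: the architecture can be trained end
to end with the hybrid loss; gradients flow through both encoders and all
skips; size-stratified evaluation and the noise-degradation ordering
(small lesions hurt most under σ = 40) behave as expected. What it does
not show: performance on real T1 MRI — the generator has no anatomy, no
bias fields, no partial-volume effects, and its contrast statistics are
far cleaner than clinical data, so absolute DSC values here do not
transfer.

## Numerical and scale choices

* Float32 weights/activations for training; float64 in gradient-check
  tests (finite differences need the head-room).
* Max-pool gradient splits evenly across ties; bilinear upsampling uses
  half-pixel-centre interpolation matrices whose adjoint is the exact
  backward pass.
* The smoke benchmark uses 200 slices at 64×64 with stratum mix
  (0.2, 0.3, 0.3, 0.2) and the CPU profile above; the noise experiment
  evaluates 120 fresh lesion-bearing slices. These sizes were chosen so
  the full suite runs comfortably on a single CPU while every stratum
  keeps double-digit slice counts.

## Known limitations

* Batch-norm statistics are per-process; there is no multi-device
  training, and very small batches make the train/eval BN gap noticeable.
* The numpy backend is CPU-bound: the 512×512 full-width configuration is
  constructible and countable in seconds, but training it at scale is not
  practical here — the architecture is the contribution, the backend is a
  vehicle.
* The published slice counts of the reference dataset (33,264 train /
  4,158 test) are not consistent with its 229 cases × 189 slices at
  8:1:1; the case-level split is kept and those counts are not reproduced.
* Exact ASPP rates, SE placement and skip-merge operator are conventions
  documented here, not published facts; they are concat-per-level,
  per-encoder-block SE, and DeepLab-style rates {1, 6, 12, 18}.
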