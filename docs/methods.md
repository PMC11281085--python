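# Methods

## Problem and model

`phubsense` recognises nine hazard states of a distracted smartphone user
("phubber") from two synchronised modalities: a front-scene photograph and a
6 s window of triaxial (50 Hz) acceleration. A hazard state is a motion
regime × scene context combination (e.g. *walking + zebra crossing*,
*stairs + darkness*). The model is a dual-branch fusion network:

1. **Environment branch** — an RGB image resized to 192 px (base
   resolution 224 × resolution factor β = 6/7) passes through a
   depthwise-separable convolutional backbone (five blocks, 13
   depthwise-separable units, ×32 total downsampling, width factor α̂ = 1),
   producing a 6×6×1024 feature map that global-average-pools to a
   **1024-element descriptor**.
2. **Motion branch** — the acceleration window is collapsed to one series by
   the X−Y−Z axis subtraction (the reduction with the highest mean signal
   energy on the synthetic regimes), encoded as a Gramian Angular Difference
   Field (GADF) pseudo-image, and passed through the same backbone at
   α = 0.75, giving a **768-element deep feature**. In parallel, nine
   statistics over seven derived series (X, Y, Z, V, X−Y, X−Z, Y−Z) form a
   **63-element statistical vector**, expanded by a fully connected ReLU
   layer to **256 elements**.
3. **Fusion head** — deep motion features and expanded statistics concatenate
   to 1024 and pass through a gated linear unit (GLU,
   `X ⊗ σ(XW_g + b_g)`); the result concatenates with the environment
   descriptor to a **2048-element joint vector**, reweighted by a
   squeeze-and-excitation (SE) bottleneck (ratio 16: 2048→128→2048,
   sigmoid), then an affine layer and 9-way softmax.

A separate **behaviour gate** — a depth-limited decision tree over the same
63 statistics — classifies the activity (static/walking/stairs phone use vs
anything else) from the accelerometer alone and turns the camera (and hence
the fusion model) on only during phone-use activities.

## Key formulas

- **GADF**: normalise `x̃ = ((x − max) + (x − min)) / (max − min)` into
  [−1, 1]; with `φ = arccos x̃`, the matrix is `G_ij = sin(φ_i − φ_j)`,
  computed algebraically as `outer(√(1−x̃²), x̃) − outer(x̃, √(1−x̃²))`.
  G is antisymmetric with zero diagonal; it is rendered to a raster by
  mapping [−1, 1]→[0, 1], replicating to 3 channels and bilinear resizing.
- **Statistics** (per derived series): mean, population variance, max, min,
  median (even/odd rule), bias-adjusted skewness `n/((n−1)(n−2)) Σz³`,
  excess kurtosis `n(n+1)/((n−1)(n−2)(n−3)) Σz⁴ − 3(n−1)²/((n−2)(n−3))`,
  interquartile range (linear-interpolated quartiles), and coefficient of
  variation σ/μ. σ is the square root of the *population* variance
  throughout. Series with zero spread, or near-zero mean (for Cv), raise
  `UndefinedStatisticError` rather than returning noise.
- **Training**: cross-entropy loss (probabilities clamped at 1e−12 with a
  warning), SGD with momentum `υ_t = γ υ_{t−1} + η ∇`, `θ ← θ − υ_t`,
  He-uniform initialisation, batch normalisation with running statistics,
  and best-validation-epoch parameter restore.

## Parameters and defaults

| Parameter | Default | Why |
|---|---|---|
| α (motion width factor) | 0.75 | printed design point; shrinks motion channels (1024→768) |
| β (resolution factor) | 6/7 | printed design point; 224→192 input |
| SE ratio | 16 | standard bottleneck ratio; 2048→128→2048 |
| stat expansion | 63→256 | printed expansion size |
| window / step | 6 s / 3 s | protocol; 50% overlap between neighbours |
| sampling rate | 50 Hz | protocol |
| learning rate / momentum | 0.01 / 0.9 | unstated in the source method; conventional SGD defaults, configurable |
| batch / epochs | 32 / 30 | unstated; conventional defaults, configurable |
| gate tree | gini, depth ≤ 8, leaf ≥ 5 | small, auditable tree; exported as JSON |

The default model has **6,634,425 parameters** (the printed total of
6,874,567 is treated as an order-of-magnitude sanity window, since the
original layer-by-layer table is not fully reconstructible).

## Synthetic data generator

No real recordings ship with the package; a seeded generator emulates the
study conditions (30 subjects × 300 image–window pairs, nine balanced
classes, subject-wise grouping):

- **Acceleration**: gravity (9.81 m/s²) on the X axis plus a regime-specific
  oscillation — walking 1.7 Hz (amplitude 1.2), stair use 1.3 Hz (amplitude
  2.16 with a 0.45 harmonic), static near-zero (noise 0.05). Y and Z carry
  antiphase fractions of the oscillation so the X−Y−Z reduction has the
  highest signal energy, mirroring the reduction-selection result. Each
  subject draws an amplitude jitter U(0.85, 1.15) and a frequency offset
  U(−0.15, 0.15) Hz, so subjects differ systematically.
- **Scenes**: procedural rasters per context — stair bands with nosing
  shadows, zebra stripes, wet ground (bright specular blobs), darkness
  (mean luminance < 0.15) — with context-specific colour tints.
- Samples materialise lazily from per-sample seeds, so the full 9000-pair
  protocol is cheap to enumerate and any single pair is reproducible.

The generator's class structure is separable by construction; held-out
accuracy on it validates that the pipeline learns, not that the published
real-data accuracy (0.9598) is reproduced — that depends on a private
30-volunteer dataset.

## Numerical choices

- The network stack is pure numpy with explicit forward/backward passes
  (no deep-learning framework is available in the target environment).
  Convolutions use im2col with stride tricks; layers preserve input dtype,
  so float64 gradient checking is exact (central differences at eps = 1e−8
  match analytic gradients to ~1e−8 relative) while production runs in
  float32.
- GADF normalisation clamps |x̃| ≤ 1 within 1e−9 before arccos; constant
  series are rejected (`DegenerateSeriesError`).
- Quantiles use numpy's linear interpolation; medians use the explicit
  even/odd rule; both are oracle-tested against brute-force
  implementations.
- Zero-spread detection is exact (`max == min`), not tolerance-based.

## Evaluation protocol

Subjects are shuffled into 10 groups of 3; each group is the test set of
one fold and the rest split 7:2 into train and validation
(subject-disjoint, asserted at runtime). Metrics: multi-class accuracy
(trace of the confusion matrix over its sum), one-vs-rest precision,
recall and F1 per class, and macro-F1. An ablation harness trains the
seven input combinations (RGB / GADF / stats and their unions).

## Limitations

- Synthetic data only: results demonstrate pipeline correctness and
  learnability, not field performance.
- The numpy stack is CPU-bound; protocol-scale (9000-pair, 10-fold)
  training is possible but slow, so shipped checks run a scaled
  configuration (2 subjects × 90 pairs at 96 px).
- The original layer table (6,874,567 parameters) is not exactly
  reconstructible from the text; this implementation's 6.63 M is validated
  against a sanity window instead.
- The behaviour gate is trained on the same synthetic regimes it is tested
  on; its ≥ 0.90 accuracy is a separability check, not a field estimate.
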