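# Methods

`bloomcast` forecasts the next day of a chlorophyll-a concentration image
series at pixel level. This note records the models and procedures the
package implements, the choices made where the design was genuinely open,
and what the synthetic test bed does and does not establish.

## Problem setting

The input is a date-indexed series of color-mapped chlorophyll-a rasters of
a lake, as produced by satellite inversion: each pixel carries one of nine
display colors ("grades"), and a per-image legend maps every grade to a
concentration band in µg/L. Real series of this kind have three defects
that must be removed before sequence modelling:

1. the concentration band behind a given grade drifts between images
   (inversion differences between acquisitions);
2. cloud cover and inversion anomalies blank out regions (gray/black/white
   sentinel pixels);
3. acquisition dates are irregular, so the series is not sampled daily.

## Preprocessing

**Scale unification.** The unified legend takes, for grade *i*, the mean of
the grade-*i* minima and the mean of the grade-*i* maxima over all input
legends. Each image's grade *j* is then re-mapped to the unified grade
minimising the Euclidean distance
√((max_j − max_i)² + (min_j − min_i)²) between (min, max) pairs; ties go
to the lowest grade index so the mapping is deterministic. Water pixels
whose color is not in the image's palette are treated as anomalies and
added to the missing mask.

**Gap repair.** Missing water pixels are filled from a spatial-weight
stencil: the four edge-adjacent neighbors (Euclidean distance 1) carry
weight 1/d² = 1 and the four diagonal neighbors (distance √2) weight
1/d = 1/√2; the filled value is the weighted mean of currently-known
neighbors. Gaps are peeled layer by layer from the contour inward: every
pixel of a layer is computed from the state *before* the layer started, so
the result is independent of scan order, and the completed layer becomes
known for the next one. A missing region with no path to known water pixels
is an error ("unrepairable frame"). The stencil radius is configurable
(weights generalise as 1/d² for axis-aligned and 1/d for oblique offsets);
the default radius 1 is the 3×3 neighborhood described above.

**Daily interpolation.** A missing day m+λ between real frames at dates m
and n receives the per-pixel, per-channel linear blend
P(m) + λ·(P(n) − P(m))/(n − m). Existing frames pass through bit-identical.

Repair and interpolation operate on RGB channel values and the result is
snapped to the nearest unified-palette color (Euclidean in RGB, ties to the
lowest grade), so every output pixel is a legal concentration grade.

**Window assembly.** The daily series is cut into sliding samples of 30
consecutive input frames plus the following day's target; N frames yield
max(0, N − 30) samples (293 → 263, 75 → 45).

## Architecture

The generator is a temporal encoder in series with a spatial U-net.

**Channel attention.** M_c(F) = σ(MLP(AvgPool(F))) ∘ F: global average
pooling per channel, a two-layer perceptron (C → 8 hidden, ReLU → C) and a
sigmoid give one weight per channel, which rescales the feature map.

**Attention-gated ConvGRU** (32 filters, 4×4 kernels by default). Per step:

    R_t = X_t∗W_xr + H_{t−1}∗W_hr + b_r        r_t = σ(M_c(R_t))
    Z_t = X_t∗W_xz + H_{t−1}∗W_hz + b_z        z_t = σ(M_c(Z_t))
    H̃_t = tanh(X_t∗W_xh + (r_t ∘ H_{t−1})∗W_hh + b_h)
    H_t = z_t ∘ H_{t−1} + (1 − z_t) ∘ H̃_t

Two deliberate readings where sources of this family of models are
ambiguous: the update combination uses the attention-gated z_t in both
terms (a convex combination, which keeps the hidden state bounded), and the
candidate state passes through tanh. Reset and update gates get separate
attention MLPs by default (a flag shares one). Thirty frames are folded
from an all-zero initial state into one hidden map, which enters the U-net
after a LeakyReLU.

**Residual U-net.** A stride-1 stem convolution (32 channels) is followed
by seven stride-2 down-sampling layers (64, 128, 256, 256, 256, 256, 512
channels, 3×3 kernels), so inputs must be divisible by 2⁷ = 128 per side.
Every down layer is conv + batch norm + LeakyReLU (slope 0.2) followed by a
residual bottleneck: a 1×1 convolution to C/2 channels and a 3×3
convolution back to C (the second convolution has twice the kernels of the
first), each conv + BN + LeakyReLU, with the block input added to the
output. Seven up-sampling layers (4×4 stride-2 transposed conv + BN +
LeakyReLU + dropout 0.5 + a stride-1 3×3 conv block; 256, 256, 256, 256,
128, 64, 32 channels) mirror the down path with U-net skip concatenation.
The output layer is a 4×4 stride-1 convolution to 3 channels with tanh.
Stride-1 convolutions use "same"-style (asymmetric where needed) zero
padding; stride-2 layers use padding 1 so they exactly halve each side.

**PatchGAN discriminator.** The candidate frame is stacked on the channel
axis with the 30 historical frames (93 channels for RGB) and passed through
four 4×4 stride-2 convolutions (32, 64, 128, 256 channels; BN on all but
the first, a flag adds it) and a 4×4 stride-1 sigmoid output convolution.
At 128×128 input this yields a 7×7 patch probability map; the scalar score
is its mean.

## Training

Adam (learning rate 0.001, β₁ = 0.5, β₂ = 0.999), batch size 1, with the
standard conditional-GAN objective:

    L_D = ½·[BCE(D(real|h), 1) + BCE(D(fake|h), 0)]
    L_G = BCE(D(fake|h), 1) + λ_L1 · mean|fake − real|

λ_L1 = 100 by default. Frames are normalised per channel to [−1, 1];
predictions are denormalised and snapped to the unified palette, so
forecast pixels are always legal grades, and dated one day after the
history's end. Windows are split chronologically with the final 10% held
out for validation; the generator weights with the best validation L1 are
kept. Weights are initialised from a truncated normal (σ = 0.02, redrawn
beyond 2σ) with an explicit seeded RNG, so builds and training runs are
bit-reproducible on CPU.

The network stack (2-D convolution and transposed convolution via an
im2col/col2im adjoint pair, batch normalisation, dropout, Adam) runs on a
compact reverse-mode autodiff core over numpy arrays
(`bloomcast.autodiff`); convolution patch matrices are recomputed during
the backward pass rather than retained, which keeps the live graph small
enough for long 30-step recurrences on one CPU.

## Metrics

SSIM (Gaussian 11×11 window, σ = 1.5, k₁ = 0.01, k₂ = 0.03, 255 dynamic
range), PSNR = 10·log₁₀(255²/MSE) with identical images reported as a
100 dB cap, cosine similarity of the flattened frames, and mutual
information of the 256-bin joint gray-level histogram (bits by default,
nats on request). All four are computed on the Rec. 601 luminance
Y = 0.299R + 0.587G + 0.114B, since per-channel versus luminance evaluation
was an open choice and luminance matches the metrics' standard usage.
Series evaluation reports per-frame values plus the mean and maximum of
each metric.

## Synthetic test bed

The generator emulates the structure of lake imagery: a perturbed
super-ellipse lake on a land background; a drifting 2-D Gaussian bloom with
a sinusoidally varying amplitude (base 8 µg/L, peak amplitude 70 µg/L,
σ = 22 px, drift ≈ 0.7 px/day — a slow translation a reduced model can
learn); quantisation to a 9-grade palette over bands 0–5–10–15–20–30–40–
60–80–120 µg/L; per-image multiplicative legend jitter (σ = 5%) on the
reported concentration bounds; gray/black cloud blobs (radius 4–14 px,
35% of frames) and white anomaly speckles (0.2% of water pixels); and
random day dropping at rate 0.76 over a 75-day span, emulating a series in
which roughly 18 of 75 days survive as acquisitions. Legend jitter is
metadata-only — colors are assigned from the base bands — which encodes
inversion uncertainty about what each color means and gives the scoring
contract that untouched pixels pass through with grade accuracy exactly 1.

`score_preprocessing` reports grade accuracy against the clean daily truth
in three strata: untouched, inpainted (spatial-weight repair) and
interpolated pixel-days. A global-mean-fill baseline is provided for
comparison.

What the synthetic bed does **not** show: real bloom dynamics are not a
translating Gaussian (wind-driven advection, patchiness, regime shifts);
clouds correlate across days; inversion noise is spatially structured; and
the published full-scale benchmark values require the real multi-year lake
dataset and long GPU training. Passing tests here demonstrate the
correctness of the pipeline's algebra and the learning capacity of the
architecture, not field-scale forecast skill.

## Problem sizes and numerical choices

Desk-scale defaults keep everything on one CPU: 128×128 frames (the
smallest legal size for seven halvings), the reduced architecture
(ConvGRU filters 8, all channel widths divided by 4) for training
experiments, 5-window training runs of 200 iterations for the learning
check, and 40 randomized instances up to 12×12 for the repair oracle.
Tolerances: repair matches its brute-force oracle to 1e-9 per channel
(float64); vectorised layers match naive equation transcriptions to 1e-6;
BCE probabilities are clamped to [1e-7, 1 − 1e-7]; batch norm uses
ε = 1e-5 and momentum 0.1. Degenerate inputs fail loudly: empty legend
lists, heterogeneous grade counts, duplicate dates, unrepairable frames,
zero-norm images in cosine similarity, non-divisible spatial sizes, and
non-finite losses all raise with a named cause.

## Known limitations

* Batch size 1 with batch normalisation means the 1×1 bottleneck map
  normalises to zero; information still flows through skip connections
  (the usual conditional-GAN behaviour), but the bottleneck itself is
  uninformative.
* The CPU engine is written for correctness and reproducibility first;
  full-size (32-filter, 512-channel) training is possible but slow, and the
  package's training experiments use the reduced architecture.
* Single-step forecasting only: no autoregressive multi-day rollout
  guarantees are made.
* The lake mask is inferred from palette membership when not supplied, so
  a cloud over land would be treated as water; synthetic clouds are placed
  over water only.
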