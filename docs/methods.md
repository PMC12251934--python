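# Methods

This note records the model implemented by `vimsa`, the assumptions baked
into it, the defaults and why, and the numerical and design choices made
where the design was genuinely open.

## Problem and model

The task is single-point keypoint regression: given a single-channel eye
image, predict the pupil-center column/row (x, y) in pixels.  Coordinates
are 0-based with origin at the top-left, x = column, y = row, pixel
centers at integer coordinates; labels are floats.

The pipeline is:

1. **Patch fusion** (`vimsa.patch_embed`).  An h×w image (default working
   frame 320×240) is tiled into non-overlapping p×p patches (default
   p = 16, so J = (240/16)·(320/16) = 300), each flattened row-major and
   projected to a D-dimensional token (default D = 192); a learnable J×D
   positional table initialized Normal(0, 0.02) is added.  One learnable
   scalar per patch is concatenated as the last feature channel, giving
   the fused B×J×(D+1) sequence.  No class token is used — the head pools
   patch features instead.  Patch-weight initializations:
   - `fixed`: all ones;
   - `random`: i.i.d. uniform on [1e-5, 1];
   - `gaussian` (default): mean profile exp(−d²/(2σ_s²)) over the
     distance d from each patch center to the image center, peak 1, with
     σ_s = 15 px — the central 30×30-pixel region spans ±1σ — plus
     i.i.d. Normal(0, σ_n) noise, σ_n = 0.1, so initial weights are not
     tied.  A noise σ of order 1 would drown the 0–1 spatial profile,
     which is why the noise scale is an order of magnitude below the
     peak; both σ_s and σ_n are configuration fields.
2. **Encoder** (`vimsa.encoder`).  n_layers (default 4) bidirectional
   blocks at model width M = D+1.  Each block: LayerNorm (feature-wise,
   learnable affine) → two linear expansions x, z: M→H → forward and
   backward pipelines on x → SiLU(z) gates both direction outputs (one
   shared z per block, matching the two gate arrows of the architecture
   diagram) → sum → linear H→M → skip connection.  Each direction runs
   multi-head self-attention (the token mixer; 12 heads by default),
   SiLU, then the selective state-space scan.  The backward path reverses
   the sequence before its pipeline and reverses the result back, with
   its own parameters: the two directions share an architecture, not
   weights.  H defaults to 2·M rounded **up** to the next multiple of
   n_heads so the head split is exact (2·M itself is generally not
   divisible by the head count).  A depthwise 1-D convolution mixer
   (`mixer="conv1d"`, kernel 3) is available as the plain-ViM ablation.
3. **Selective scan.**  Per channel, h_t = Ād_t ∘ h_{t−1} + B̄d_t·x_t,
   y_t = ⟨C_t, h_t⟩ with h_0 = 0 and S state channels per feature
   (default S = 16).  The discrete matrices are input-dependent:
   Δ_t = softplus(W_Δ·x_t + b_Δ), B_t = W_B·x_t + b_B,
   C_t = W_C·x_t + b_C, Ād_t = exp(Δ_t·A) and B̄d_t = Δ_t·B_t, with A
   stored in log space as A = −exp(A_log) so every entry of Ād_t lies
   strictly in (0, 1) for finite input — the zero-input state always
   decays.  A_log is initialized to log(1..S) per channel and b_Δ so that
   softplus(b_Δ) is log-uniform on [1e-3, 1e-1], the customary selective
   state-space initialization.  **Timing convention:** the output reads
   the post-update state, so y_1 depends on x_1; the alternative
   (pre-update read) would waste the first input entirely.  The
   sequential recurrence is the normative semantics; the fused training
   primitive is tested against it and its hand-derived backward pass
   against finite differences.
4. **Head** (`vimsa.head`).  The weight channel is split off and folded
   into the pooling sum: feature_d = (Σ_j w_j·t_{j,d})/J.  A literal
   global average over J followed by a length-J weighting is
   dimensionally impossible (the pooled vector has length D, not J), so
   the weights modulate the average itself; at uniform unit weights this
   is exactly global average pooling.  Division by J rather than Σw keeps
   the pooling linear in w and the gradient scale stable
   (`pool_norm="weight_sum"` gives the alternative).  A two-layer MLP
   (D → D/2, SiLU, D/2 → 2) produces the coordinates.  The network
   output is mapped through a fixed affine transform, prediction =
   image_center + s·MLP(x) with s = (w+h)/4: the optimizer then starts
   at the image center and works in O(1) units instead of dragging an
   output bias across tens of pixels at ~learning-rate speed per step.
   The loss and all reported metrics remain in pixels.

**Initialization.**  Every linear map (patch projection, Q/K/V/output
projections, encoder expansions, SSM generators, head MLP) draws
zero-mean Gaussian weights at fan-in scale, std = 1/√fan_in, with zero
biases; the positional table uses std 0.02 and the SSM-specific
parameters the customary selective-scan init described above.  Fan-in
scaling keeps activations and gradients O(1) at the small widths this
package targets — a fixed small std (e.g. 0.02, customary for
1000-wide transformer stacks) starves signal propagation at widths of
32–64 and measurably stalls training.

## Attention and the FFT route

Scaled dot-product attention is softmax(Q·Kᵀ·scale)·V per head.  The
scale is 1/√d_head by default.  The wording that pairs the softmax
denominator with "the number of heads" conflicts with standard notation,
where d_k is the key width; 1/√d_head is the established stabilizing
choice, and `scale_mode="sqrt_num_heads"` makes the literal reading
runnable.

At inference both matrix products run through the outer-product/FFT
route (`vimsa.fourier`): columns of A and rows of B are zero-padded to a
common power-of-two length L, transformed with a hand-rolled radix-2
Cooley–Tukey FFT, combined as frequency-domain outer products, summed
over the shared index (the DFT is linear, so accumulating before a single
2-D inverse transform is mathematically identical to inverting each
rank-1 term separately, and costs far fewer transforms), inverted, and
cropped to m×p.  Zero-padding is exact here — the identity
ψ(a⊗b) = ψ(a)⊗ψ(b) holds at the padded length, and no circular
convolution is involved.  The softmax is applied in the time domain on
the reconstructed score matrix, numerically stabilized by row-max
subtraction.  Training differentiates through the dense route for
efficiency; the acceptance suite asserts dense/FFT forward agreement to
1e-5, so the routes are interchangeable.

`count_operations` reports the operation accounting for an N×N product:
N³ multiplications and N³−N² additions for the direct triple loop, and
the nominal complexity formulas N²+N·log₂N multiplications and
N·log₂N additions for the FFT route.  An instrumented counter measures
the multiplications the implementation actually performs; the measured
count is reported alongside the formulas and is substantially larger —
the frequency-domain accumulation alone is N² per rank-1 term — so the
claimed totals are surfaced as stated, not asserted as achieved.

## Training protocol

Defaults follow the selected protocol: AdamW (β = 0.9/0.999, weight
decay 0.01, applied to all parameters), batch size 4, cosine decay
lr(e) = lr_min + ½(lr_init−lr_min)(1+cos(π·min(e,T)/T)) with
lr_init = 1e-3, lr_min = 1e-5, cycle T = 100 epochs, clamped at the
minimum beyond the cycle.  Step (1e-3/1e-4/1e-5 with 40-epoch
breakpoints), exponential (γ = 0.95) and fixed schedules, and SGD
(±momentum), AdaGrad and RMSProp are provided for protocol comparisons.
The mini-batch loss is the RMSE formula with N = batch size (a 1e-12
floor inside the square root guards the gradient at exact zero error).
Learning rates update at epoch granularity; there is no early stopping;
the default epoch budget is 100 (one cosine cycle).  Runs are pure
functions of (model seed, data, training seed): data order, init and
optimizer state are all seeded, and everything is float64 NumPy, so
histories are bit-reproducible on a fixed platform.

DR@k counts a prediction correct when its Euclidean distance to truth is
≤ k ("within k pixels" read boundary-inclusive; configurable).  Distance
is Euclidean because the paired RMSE is Euclidean; per-axis error is
never used.

## Synthetic data

The generator emulates the photometric structure detectors of this kind
rely on: a dark elliptical pupil (a pixel belongs to the pupil iff its
center satisfies the rotated-ellipse inequality ≤ 1; no anti-aliasing, so
noise-free centroids are exact), a concentric iris disc at 2.2× the pupil
semi-major axis, a brighter sclera field, and nuisance effects mirroring
the artifacts catalogued for real recordings (specular reflections, poor
illumination, mascara): one bright glint disc overlapping the pupil, a
dark occluder band across the top, an additive linear illumination
gradient, and i.i.d. Gaussian pixel noise, clipped to [0, 255].  Default
intensities (pupil 30, iris 100, sclera 200 gray levels) keep the
ordering pupil < iris < sclera that the detector assumes; default pupil
semi-axes 15–40 px on the 320×240 frame match typical near-infrared eye
crops, and the margin keeps centers at least one maximal pupil radius
from the border.  Preprocessing follows the conventions of the public
pupil corpora: inputs that are an exact integer multiple of the working
frame are downscaled by area averaging with labels divided by the factor
(640×480 → 320×240 is the 2× case); anything else is center-cropped with
labels translated by the offset, and a sample whose label leaves the
crop is flagged discarded rather than clamped — clamping would corrupt
the regression target.  Datasets split 85/15 by seeded permutation with
⌊n·f⌉ training items.

What the generator does **not** model: eyelash/skin texture, photometric
sensor noise structure, perspective distortion of off-axis cameras,
video temporal correlation, and pupil-absent frames (the model has no
"absent" output class, so such frames have no defined target).  Passing
tests on synthetic data therefore demonstrate that the architecture,
gradients, and training protocol work end to end — not field accuracy on
real recordings.

## Scaled-down experiment sizes

The end-to-end experiments in the test suite and `scripts/acceptance.py`
use a reduced instance chosen as the package's standard desk-scale
configuration: 64×48 frames, 8×8 patches (J = 48), D = 32, 2 layers, 4
heads, S = 8, H = 64, 200 clean training images (no noise, glints,
occluders or gradient), 50 held-out images, 150 epochs of the default
protocol.  With these sizes a full training run takes a few minutes on
one CPU core.  The full-scale defaults (320×240, D = 192, 12 heads, 4
layers) are the intended configuration for real experiments.

## Known limitations

- The FFT attention route is quadratic in practice despite the nominal
  complexity formulas (see the operation accounting above); it is the
  normative inference path because route equivalence, not wall-clock
  speed, is the contract here.
- The sequential scan is a Python loop over timesteps; J in the hundreds
  is fine, video-rate workloads would want a compiled kernel.
- Hyperparameters D, H, S and the layer count of the full-scale model
  are package defaults, not values taken from any reference system.
- The generator's nuisances are geometric idealizations; robustness
  numbers on it should not be quoted as robustness on real data.
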