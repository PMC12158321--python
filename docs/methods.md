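# Methods

This note documents the models implemented in `midirseg`, the parameters
that matter, the synthetic data the tests run on, and the design choices
made where the method description left the design open.

## Mixture background model

Each pixel holds `K` Gaussian intensity modes `(ω, μ, σ²)` kept sorted by
`ω/σ²` (heavy, tight modes first; ties broken by the stable sort, so runs
are bit-reproducible). Per frame and pixel:

* **Match**: the first ranked mode with `|m_t − μ| ≤ 2.5 σ` (the
  multiplier is configurable). In 3-channel mode all channels must
  satisfy the bound and the variance is shared across channels.
* **Classify**: the background is the shortest ranked prefix whose
  cumulative weight reaches `T`; a pixel is foreground when it matches no
  mode or only a mode outside that prefix.
* **Update**: matched `ω ← (1−α)ω + α`, `μ ← (1−ρ)μ + ρ m_t`,
  `σ² ← (1−ρ)σ² + ρ(m_t − μ_old)²`; unmatched modes keep `μ, σ²` and decay
  `ω ← (1−α)ω`. On no-match the lowest-ranked mode is replaced by
  `(ω₀, m_t, σ₀²)`. Weights are renormalised and modes re-sorted after
  every update.

The second-order rate ρ is not pinned down by the usual presentation of
the model; the default here is the common simplification **ρ = α**
(deterministic and testable), with `rho_mode="scaled_pdf"`
(`ρ = α·η(m_t; μ, σ)`) available for fidelity experiments.

Defaults, with units: `α = 0.005` (a config value of −1, the conventional
"auto" flag, maps to this default), `T = 0.75` (restricted to [0.5, 1]),
match multiplier 2.5, `σ₀² = 225` intensity², `ω₀ = 0.05`, variance floor
1.0 intensity² (prevents σ → 0 on constant video), `k_init = 3`.

Two contracts worth noting: `α = 0` freezes the model *bit-exactly*
(weight decay, the no-match replacement and even the renormalisation ulp
drift are all suppressed where the effective per-pixel α is 0 — the
SSIM schedule produces exactly 0 for identical consecutive crops), and
after every step the per-pixel weights sum to 1 within 1e-9 with the
ranking invariant intact. A straight-line scalar reference implementation
of the same rules lives in the test suite and the vectorised path is
checked against it on random single-pixel histories.

## Temporal adaptation

* **ROI**: the plain model runs on the first 100 frames (`warmup_frames`);
  the fixed ROI is the tight bounding box of all warm-up detections plus a
  5-px margin. An empty warm-up union degrades to a whole-frame ROI with
  a logged warning.
* **Learning-rate schedule**: global (single-window) SSIM between
  consecutive ROI crops, `XSSIM = (2μⱼμₖ + C₁)(2σⱼₖ + C₂) /
  ((μⱼ² + μₖ² + C₁)(σⱼ² + σₖ² + C₂))` with `C₁ = (0.01·255)²`,
  `C₂ = (0.03·255)²`, then `α = (1 − SSIM)/80` clipped to [0, 1], applied
  to in-ROI pixels; pixels outside the ROI keep the default α. The
  schedule is monotone non-increasing in SSIM with range [0, 1/40].
* **Component counts**: every ROI pixel keeps a rolling 100-frame 256-bin
  histogram. Peaks are plateau-aware strict local maxima (the first bin
  of a flat top counts once; the histogram ends behave as strictly lower
  neighbours so boundary modes count). Neighbouring peaks closer than 30
  bins merge greedily left-to-right into the taller one. The surviving
  count, clamped to `[k_min, k_max] = [1, 5]`, becomes the pixel's target
  K; outside the ROI the target is 2. Shrinking drops the lowest-ranked
  modes; growth appends `(ω₀, σ₀²)` modes seeded at the histogram peak
  farthest from the existing means. Re-evaluation happens every frame but
  only pixels whose count actually changes are touched.

Why this rescues dwelling targets: a freshly absorbed target mode carries
a large variance (it was born at σ₀²), so it ranks far below the old
crisp background mode. When the merge rule collapses a low-contrast
target peak into the background peak (contrast < 30 gray levels), the
count drops and exactly those high-variance absorbed modes are pruned —
the pixel turns foreground again. The packaged ablation (plain model vs
+LR vs fully adaptive) shows each feature strictly increasing recall on
the dwelling-flock scene.

## Segmentation network

A UNet-family encoder–decoder: per stage two 3×3 reflect-padded
convolutions + ReLU; subsampling by a 3×3 stride-2 reflect-padded
convolution (+ReLU) in the primary variant or 2×2 max-pooling in the
baseline; a two-convolution bottleneck; decoder stages that upsample
(nearest ×2 + 3×3 convolution by default, a pure 2×2 transposed
convolution as a config switch), concatenate the symmetric encoder skip,
and apply two 3×3 convolutions; a 1×1 sigmoid head for the single
foreground class. Widths double per stage from `base_width`.

Forward, backward (im2col convolutions, reflect-pad gradient folding) and
Adam are implemented in NumPy; gradients are verified against finite
differences in the tests. Training is deterministic under a fixed seed
and a fixed BLAS/thread configuration (the documented contract).

Training protocol: binary cross-entropy on the sigmoid output, Adam
(default step 1e-4), batch size 2, 1000 epochs, inputs resized to
256×256, an 8:2 seeded train/validation split — every knob overridable.
**Inputs are standardised per image to zero mean and unit variance**
rather than scaled by 1/255: low-contrast thermal frames are nearly
constant, and on the raw scale the few-gray-level target contrast is
buried under the common mode — training then stalls on the
all-background solution that a heavily imbalanced cross-entropy admits.
Masks are resized with nearest neighbour (label preservation), images
bilinearly. Since the network is fully convolutional, prediction runs at
the frame's native geometry whenever its sides divide by `2^depth`, and
otherwise resizes to the spec's input size and restores the frame
geometry with nearest neighbour.

### Complexity accounting

`count_flops` sums convolution-layer costs (`Cin·k²·Cout·Hout·Wout`
multiply–accumulates; activations, pooling, interpolation and
concatenation are free). `flops_per_mac` selects the textbook convention
(2 operations per MAC, the default) or the profiler convention (1
operation per fused MAC). The **reference architectures** — depth 4,
widths 64/128/256/512 with a 512-wide bottleneck, nearest+3×3 upsampling,
grayscale input, one output class — were calibrated against the published
complexity figure of the baseline UNet under the profiler convention with
bias adds excluded (`PUBLISHED_FLOPS_CONVENTION`): 60.44 G vs the printed
60.24 G for the baseline, and 62.86 G vs 63.44 G for the strided variant,
both within 2%. The strided variant is strictly heavier than the pooling
baseline under every convention because its subsampling convolutions
replace zero-cost pooling.

## Fusion and morphology

Bitwise OR is the default fusion: the stated role of the network is to
correct the motion detector's error-prone regions (hole filling), which
an AND cannot do; AND is retained in the config for clutter-heavy scenes.
The morphology default is opening with a 3×3 ellipse (removes
sub-element speckle) then closing with a 5×5 ellipse (seals small holes).
Erosions treat the frame exterior as foreground and dilations as
background, so opening stays anti-extensive and closing extensive up to
the border. The pipeline mask is exactly
`refine_morphology(fuse_masks(bgs, net))` — no hidden stages.

## Metrics

`precision = TP/(TP+FP)`, `recall = TP/(TP+FN)`, `IOU = TP/(TP+FP+FN)`,
`accuracy = (TP+TN)/total`; empty denominators report 0 with a
`degenerate` flag. Sequence aggregation is micro-averaged (confusion
counts pooled over frames, then divided). Sharpness: Brenner
`Σ(f(x+2,y)−f(x,y))²`, Roberts `Σ(f(x+1,y+1)−f(x,y))² +
(f(x+1,y)−f(x,y+1))²`, and SMD2. The literal SMD2 formula omits absolute
values and can produce negative summands; the default follows the
standard focus-measure convention `Σ|Δv|·|Δh|`, with `signed=True`
keeping the literal signed product. All sharpness functions cast to
float first (no unsigned wraparound) and are translation-invariant and
quadratically homogeneous in contrast. `relative_difference(smaller,
reference) = (reference − smaller)/reference` with the sharper
measurement as the reference.

## Synthetic scenes

The generator emulates the regime the pipeline targets: a smooth
spline-interpolated background texture (amplitude 8) on a base level of
110, linear illumination drift (0.02 intensity/frame), Gaussian sensor
noise (σ = 3 gray levels), and warm elliptical targets 35 gray levels
above background — deliberately *below* typical global contrast but above
noise, and close enough to the background that the 30-bin peak-merge rule
treats a mixed pixel history as unimodal, which is exactly the
low-contrast situation that produces stay-holes. Targets dwell in place
with probability 0.8 per frame and otherwise take ≤2-px steps; in flock
mode they share a drifting cluster centre. An optional clutter patch
oscillates sinusoidally (period 20 frames, amplitude 10), standing in for
vegetation jitter. Masks are the exact binary target support — no
anti-aliased fringe. The named `stay_hole_benchmark` scene (four
clustered targets, 400 frames of 96×128, under 2% foreground by
construction: 4 targets × ≤60 px < 0.02 × 12288) is regenerated
identically from its seed.

What the generator does **not** model: radiometric mid-IR physics,
atmospheric scintillation, sensor fixed-pattern noise, occlusion by
terrain, target appearance changes (pose, gait) and the heavy-tailed
clutter of real vegetation. Passing the synthetic benchmarks therefore
demonstrates the mechanisms (absorption, rescue by temporal adaptation,
hole-filling fusion), not field performance.

## Scaled-down benchmark protocol

The packaged end-to-end benchmark trains a depth-3, base-width-8 network
at the scene's native 96×128 geometry on 24 synthetic pairs for 120
epochs at batch 4 with the Adam step raised to 2e-3 — the full protocol's
schedule shortened roughly eightfold, with the step size raised to
compensate. These sizes were chosen so the whole benchmark (generation,
three-arm ablation, training, 300-frame inference and fusion) completes
in minutes on a single CPU core while leaving comfortable margins on its
quality checks.

## Known limitations

* The ROI is a single fixed rectangle; scenes whose activity migrates
  out of the warm-up box degrade to the default-α path. Multi-ROI or
  moving-ROI tracking is out of scope.
* Histogram-peak counting assumes 8-bit intensities (256 bins).
* The NumPy network is sized for small training sets; the full
  256×256/1000-epoch protocol is supported but slow without vectorised
  BLAS parallelism.
* Mask-level fusion has no temporal smoothing or connected-component
  size filtering; isolated clutter that survives morphology passes
  through.
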