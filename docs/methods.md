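# Methods

This note records the modelling assumptions, numerical conventions and
design choices behind `phenocycle`, and what the synthetic experiments do
and do not establish about real satellite data.

## Input model

The unit of analysis is one pixel-year of NDVI: 24 values at 15-day
compositing, each in [−1, 1] or missing (cloud/sensor dropout). Missing
observations are carried in an explicit boolean mask — never as sentinel
numbers inside the value range — and every operation either requires or
produces gap-free series as stated in its contract.

## Reconstruction

Three stages run in a fixed order: gap filling, jump correction, smoothing.

**Gap filling** is iterative neighbour averaging. In each pass, every
missing point with at least one observed immediate neighbour becomes the
mean of its observed immediate neighbours, all replacements reading the
state at the start of the pass, so a run of missing values closes
symmetrically from both edges and a leading/trailing run copies the nearest
observed value. A 24-point series needs at most 12 passes; the default cap
of 10 passes covers every realistic cloud pattern, and if a pathological
series still has gaps at the cap, the remainder take the nearest observed
value so the postcondition (no gaps) always holds. Averaging cannot invent
local structure: a cycle whose entire bump was clouded out is unrecoverable
by construction, which is the honest behaviour.

**Jump correction** treats an adjacent difference greater than 0.4 NDVI
(strictly greater — about half the largest value crops attain) as an
artefact. The scan is a single left-to-right pass; the comparison uses the
already-corrected left value and the replacement is the midpoint of the
corrected left neighbour and the original right neighbour, `(v[i-1] +
v[i+1]) / 2`. A flagged final point has no right neighbour and copies its
left one. Two deliberate conventions: the replacement value (a "natural
rate of change" admits many readings; the neighbour midpoint is the
deterministic linear interpolant) and the single pass (re-scanning to a
fixed point can cascade corrections across the whole series; one pass is
order-stable and predictable). A single pass does not guarantee that no
adjacent difference above 0.4 remains globally — steep but genuine crop
flanks can legitimately approach the threshold.

**Smoothing** is a Savitzky–Golay filter, window 3, with boundary windows
fitted at the edges (`scipy.signal.savgol_filter(..., mode="interp")`) and
output clipped to [−1, 1]. A window-3 *quadratic* filter is the identity
transform — three points determine the fitted parabola exactly — so that
nominal configuration passes series through unchanged. We keep **order 2
(identity) as the default** and expose order 1 (a 3-point moving average)
for effective smoothing. The reasoning: a 3-point moving average attenuates
a crop bump of width ~1 composite by roughly 20%, and because the adaptive
peak threshold is 0.70 of the series maximum, that attenuation
systematically pushes the secondary peaks of low-amplitude multi-cycle
pixels below threshold while barely touching the maximum used to set it.
With 24-point series the cost of effective window-3 smoothing exceeds its
benefit for cycle counting; noise suppression is instead provided by the
jump rule and by the counting thresholds themselves, which ignore
small-amplitude wiggles by construction.

## Adaptive-threshold cycle counting

Let `m = max(series)` after reconstruction.

- `m < 0.3` (strict): the pixel is labelled 0 outright — such low greenness
  is barren land, rock, water or sparse vegetation, not active cropland.
- otherwise peaks qualify at `0.70·m` and valleys at `0.20·m`. Both bounds
  are **inclusive** (the thresholds derive from the series itself, so the
  maximum must not be excluded by floating-point error). The valley
  fraction multiplies the series maximum, parallel to the peak rule, not
  the peak threshold — the two readings differ by a factor 0.7 and the
  parallel one keeps both thresholds on one scale.
- extrema are local maxima/minima with plateaus of equal values collapsed
  to a single extremum at the plateau's first index (a flat-topped bump is
  one agronomic cycle); series endpoints are eligible extrema against their
  single neighbour; a constant series has none.
- a qualifying peak counts as a cycle when at least one qualifying valley
  lies on each side of its plateau; a peak touching a series endpoint needs
  a valley on its single inward side only. A valley may flank two adjacent
  peaks simultaneously (each peak tests its own sides independently).
- counts above 3 clamp to 3: the label set is 0–3 and a fourth cycle in 24
  composites is agronomically implausible (it would require complete
  sow-to-harvest cycles of ~90 days back to back); clamping is preferred to
  an error so map inference never aborts on a noisy pixel.

The adaptive thresholds make the count exactly invariant under amplitude
scaling `v → c·v` while `c·m` stays within [0.3, 1] — the property a fixed
NDVI cut-off lacks, and the reason a double-cropped pixel peaking at 0.45
is counted correctly where a static 0.5 threshold finds nothing.
`count_cycles_static` implements that baseline (fixed peak threshold,
valley threshold scaled by the same 0.20/0.70 ratio) for comparison.

## Synthetic phenology generator

Crop pixels follow a Gaussian-bump model:

```
v(t) = base + Σ_k A_k · exp(−(t − μ_k)² / (2σ_k²)) + weed + N(0, σ_n²)
```

clipped to [−1, 1], each point independently missing with probability
`missing_prob`. Defaults: base level 0.12 (bare-soil background), cycle
amplitudes drawn per series in [0.55, 0.9] (clean crop peaks always exceed
0.5) with per-peak jitter in [0.97, 1.03], noise sd 0.02, missing
probability 0.1. Non-crop confusers: water (flat negative NDVI in
[−0.4, −0.05]), bare soil (flat low positive), forest (high plateau
0.62–0.80 with a gentle seasonal swing and no deep valleys). Weed
contamination is a bump capped at 0.3× the main amplitude placed in the
off-season of single-cycle pixels — large enough to create a local maximum,
small enough that the adaptive threshold must reject it.

**Cycle geometry.** Defaults are one bump at centre 11.5 with width
σ = 2.0; two at 6/16 with σ = 1.3; three at 4/12/19 with σ = 1.1. These
were chosen once from the constraint structure, not fitted: for the true
label to be well defined, every inter-cycle and tail minimum must fall
below `0.20·max` *at the lowest drawn amplitude* (with base 0.12 and
A = 0.55 the valley threshold is only ≈ 0.134, so three-cycle bumps must be
narrow and integer-centred so the sampling grid hits each top exactly),
while every true peak must clear `0.70·max`. The same constraints show a
genuine trade-off: a width that keeps triple-cropping valleys clean
(σ ≈ 1.1) is too narrow to survive a cloud gap directly on a bump top —
neighbour-average filling then retains only ~66% of that peak, below the
0.70 threshold when another peak sets the maximum. No geometry satisfies
both at the lowest amplitudes, so the generator guarantees exactness on
clean data (every emitted crop series is verified against the counter at
generation time; violating parameters raise `GeneratorError`) and accepts
statistical losses for 3-cycle pixels under heavy missingness.

**Sample sets.** The extent set defaults to 75 cropland (1–3 cycles,
uniform) and 75 non-cropland (uniform over the three confusers). The
intensity set defaults to 200 series with deliberately imbalanced priors
0.4/0.3/0.2/0.1 over classes 0–3, so downstream oversampling is exercised;
true labels are recorded from the requested cycle count at generation time,
never from the counting algorithm. The raster generator lays out
rectangular fields, a river strip and a forest block over a bare
background, one shared clean curve per patch with ±2% per-pixel amplitude
jitter (fields draw amplitudes in [0.75, 0.82] — vigorous irrigated fields,
with headroom under the 0.4 jump threshold at steep flanks), then
independent per-pixel noise and missingness; georeferencing spans a
0.5° × 0.5° tile.

**What the generator does not emulate:** spatially correlated cloud cover,
mixed pixels at field boundaries, sensor saturation, double-logistic
green-up asymmetry, inter-annual drift, and crop-type-specific curve
shapes. Passing tests therefore demonstrate the internal consistency and
noise robustness of the algorithms, not their accuracy on real Sentinel-2
scenes.

## Classifiers

Features are the raw 24 reconstructed values — no phenometric summaries —
so every model sees exactly what the counting algorithm sees. Defaults:
random forest with 100 trees and unlimited depth; gradient boosting with
100 rounds, depth 6, learning rate 0.1; KNN-DTW with k = 1 and an
unconstrained warping window (DTW is the classic dynamic programme with
absolute-difference local cost; ties in the vote break by smaller mean
distance, then lower class index). Labels are encoded to a contiguous range
internally so any backend accepts sparse label sets. The harness default
protocol is a stratified 80/20 split with a fixed seed; accuracy is
reported as overall accuracy with the full confusion matrix and per-class
recall alongside, and wall time is informational only (hardware-bound,
never asserted). Class imbalance is handled by random oversampling to the
majority count, all originals retained. Recurrent models are a `plugin`
registration slot behind the same contract; none ships in the core.

## Raster conventions

Pixel (0,0) is the upper-left cell; point-in-pixel lookup uses half-open
cells; polygons take pixels whose centres fall inside. Band order is time
order. Stacks and maps are multi-band TIFF with the affine transform, CRS
string, nodata sentinel, legend and run parameters serialized as JSON in
the ImageDescription tag; finite values round-trip bit-exactly. Inference
is tiled (default 256×256) and pixels are independent, so tiling never
changes outputs; pixels with no observations at all propagate as nodata.

## Problem sizes and tolerances

The test suite validates the counter against a brute-force prose enumerator
on 10,000 random series of length ≤ 8 over a 0.1-spaced value grid, and DTW
against exhaustive path enumeration on 1,000 pairs of length ≤ 6. Label
recovery uses 200 clean series (exact recovery required) and 500 series at
noise sd 0.05 with 20% missingness (≥ 90% required; observed ≈ 93%, with
3-cycle pixels the dominant loss as analysed above). End-to-end map checks
use a 32×32 scene: at zero noise the threshold-method intensity map must
equal the truth map pixel-for-pixel, and a random-forest extent map trained
on 150 default-noise samples must agree with truth on ≥ 90% of pixels.
Savitzky–Golay polynomial reproduction is asserted to 1e−9; the window-3
quadratic identity to 1e−12.

## Known limitations

- Intensity labels saturate at 3; genuinely higher cycle counts (rare
  horticultural systems) are clamped.
- A cycle whose bump is entirely hidden by clouds cannot be recovered by
  neighbour averaging; 3-cycle pixels under ~20% missingness lose roughly
  half their third-cycle detections for exactly this reason.
- The jump rule's single pass may leave residual large differences; the
  fixed 0.4 threshold is calibrated to crop NDVI dynamics and will flag
  genuine abrupt events (flooding, harvest of very vigorous crops) as
  artefacts.
- KNN-DTW is quadratic per comparison and linear in the training set per
  query; it is intended for sample-scale evaluation, not full-map
  inference.
- TIFF georeferencing is self-describing JSON, not GeoTIFF tags; GIS tools
  will read the pixels but not the projection without a translation step.
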