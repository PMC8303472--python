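# Methods

## The score and its assumptions

The calcium score of one echocardiographic still image is the set of pixels
inside an operator-chosen aortic-valve ROI whose (blurred) intensity exceeds
an adaptive threshold, summarized as a white-pixel count plus raw and
normalized mean/median intensities. The method assumes:

* calcium is the brightest tissue in the image, and blood pools the darkest;
* acquisition and post-processing settings act, to first order, as an
  *additive* brightness shift on the display scale within the usable range
  (the linear WW/WL mapping makes level changes exactly additive up to the
  255/WW slope; gains are additive by definition);
* blood intensity is stable across settings, so a blood-pool ROI measures
  the shift.

Under these assumptions, thresholding at `T0 + d̄` (base threshold plus the
dark-reference mean) yields a mask invariant to the shift. The equivalent
formulation — subtract `d̄` from every pixel, threshold at `T0` — produces
the same mask because strict inequality is translation-invariant; the
implementation shifts the threshold instead of the image because it is
lossless (no clamping at 0) and cheaper, and subtracts `d̄` only when
reporting normalized intensities. This equivalence is itself a test.

## Pipeline stages and parameters

| parameter | default | units | role |
|---|---|---|---|
| `blur_kernel` | 11 | px | median-filter side; speckle suppression before segmentation |
| `base_threshold` | 160 | grey levels | fixed calcium cutoff before the adaptive shift (140 reproduces the first-pass fixed-threshold variant) |
| `dilation_kernel`, `dilation_iterations` | 3, 1 | px, – | recover blob pixels eroded by the blur |
| `clahe_clip`, `clahe_tiles` | 2.0, 8 | –, tiles/axis | visualization aid only; not a default stage |

Stage order: load → (optional) subtract outside-sector mean → median blur →
estimate dark reference **on the blurred, gain-compensated image** (the
image actually thresholded) → binarize at `T0 + d̄` (strict `>`; a pixel
equal to the threshold is background) → (optional) dilate → extract white
coordinates in the valve ROI → quantify on the **un-blurred** gain-compensated
image. Blur is noise cleanup for detection; reported intensities must not be
smoothed. Whole-image gain compensation (rather than ROI-only) follows the
process-flow reading of the gain-removal stage.

Numerical conventions, stated once and used everywhere: 0-based, row-major,
half-open ROIs; integer images are produced by rounding half away from zero;
colour inputs collapse to luminance with BT.601 weights; median blur pads by
edge replication (avoiding dark-border artifacts that would bias
outside-sector means); dilation uses a square structuring element.
Histogram equalization uses the inclusive cumulative `H'(i) = Σ_{j≤i} H(j)`
so the brightest occupied bin maps to 255 (the strict variant is available
behind a flag). CLAHE delegates to scikit-image's implementation, with the
clip limit exposed in the familiar multiplier convention (converted
internally as `clip/256`).

Degenerate inputs are errors, not silent defaults: a dark-reference mean
above the base threshold (mis-placed ROI), an adaptive threshold reaching
255 (nothing could be calcium), ROIs leaving the image, even kernels. An
outside-sector mean above 128 and negative normalized intensities trigger
warnings. Empty masks report count 0 with *absent* statistics, never zeros.
Disconnected calcium regions inside the valve ROI are pooled into one count,
with per-component sizes (8-connectivity) reported as a convenience.

## The phantom

The generator emulates the statistical structure the pipeline relies on —
not ultrasound physics. A scene is an annular wedge (apex top-center,
half-angle 35°, radius 180 on a 192×192 canvas) of speckled tissue
containing elliptical blood cavities and elliptical calcium blobs whose
rasterized pixel sets, computed before noise, are the exact ground truth.
Acquisition applies, in order: multiplicative gamma speckle with mean 1
(shape `1/σ²`, the standard first-order ultrasound texture model; σ defaults
to 0.05 and scales inversely with the ultrasound-frequency analogue), a
power-law contrast exponent (image-compression analogue; vendor transfer
curves are proprietary, so any smooth monotone family suffices), an additive
post-processing gain applied everywhere (so the outside-sector background
equals the gain exactly), the linear WW/WL mapping, and 8-bit quantization.
One master seed spawns per-image streams, making grids reproducible
element-wise.

Two stock scenes are provided. The *default scene* (tissue 80, blood 18,
calcium 220, blob area 445 px) matches the default base threshold 160 and is
used for parameter-recovery and count studies under identity display
mapping. The *invariance scene* (tissue 70, blood 15, calcium 150) is used
for the windowing study, where the 9-variant grid — gains {0, 20, 40} ×
window levels {75, 100, 125} at width 250 — leaves raw-intensity headroom
only up to `WL_min + WW/2 − gain_max = 160` before display saturation; its
base threshold is set to 110, the tissue/calcium midpoint, by the same
calibration logic that fixed the clinical threshold at 160 for real
scanners' brightness scales. Noiselessly, nothing in that scene saturates
under the brightest variant; with speckle, only the blob's upper noise tail
can graze 255, a sub-grey-level effect on the mean.

What the phantom does **not** model: wave propagation, refraction, acoustic
shadowing distal to calcium, depth-dependent resolution, and anatomy beyond
"dark cavities in bright tissue". Passing tests therefore demonstrate the
pipeline's algorithmic correctness and its invariance to the modelled
acquisition transforms — not clinical accuracy on patient images, which the
packaged 12-patient validation statistics address separately.

## Calibration and tolerances

* **Count band.** With an 11×11 median blur, a convex blob shrinks mainly at
  high-curvature boundary segments and a single 3×3 dilation adds a
  one-pixel ring, so the pipeline count sits slightly above truth
  (445 → 497, ratio 1.12, on the default scene). The calibrated acceptance
  band is [0.8 A, 1.3 A] of the true area A; across 100 seeded phantoms with
  random gains and blood levels every run lands inside it.
* **Estimator bias.** Gain and dark-reference estimators are exact
  noiselessly; under speckle and quantization their bias across 100 seeds
  stays below 0.5 grey levels (quantization alone bounds a uniform-gain
  estimate's error by ±0.5).
* **Invariance.** Across the 9-variant grid the normalized mean calcium
  intensity varies by well under 1 grey level around its across-variant mean
  (≈0.5–0.7 depending on seed), against a tolerance of 3 — the residual
  comes from per-variant speckle realizations, quantization of the offset,
  and the 255/250 window slope.
* **Statistics conventions.** Stability across a fixed, fully observed set
  of acquisitions is a population SD (divisor n); recomputing the packaged
  stability table confirms divisor n reproduces its printed 5.78/6.94 while
  n−1 would give 5.90/7.09. The agreement p-value is the standard two-sided
  t-test on r with n−2 degrees of freedom. The coefficient of determination
  is reported as r² (0.854 for the packaged validation set, r = 0.924).

## Problem sizes

Tests and the acceptance study use 192×192 phantoms (sector, blobs and blur
kernel scaled coherently), 9-variant grids, 100-seed recovery runs, and 200
random ≤32×32 images for the exact-equivalence check against the naive
per-pixel reference — sizes chosen so the full suite runs in well under a
minute while every estimate's Monte-Carlo error stays far below the
tolerance it is checked against.

## Known limitations

* Semi-automatic by design: ROI placement encodes expert anatomy knowledge;
  there is no automatic left-atrium or valve localization.
* Counts are pixel areas; conversion to cm² would need probe calibration
  metadata that the method deliberately avoids (validation is against
  expert planimetry instead).
* The additive-shift assumption breaks near display saturation: calcium
  already clipped at 255 in the source image cannot be normalized back.
* Multi-frame (cine-loop) data, 3-D echo and vendor-specific compression
  curves are out of scope; DICOM support extracts a single frame only.
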