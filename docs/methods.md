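# Methods

## The hue-spectrum model

A color camera reports each pixel as red, green and blue intensities in
0–255. Projecting the RGB cube onto the plane orthogonal to the gray axis,

```
x = R − (G + B)/2
y = (√3/2)(G − B)
```

gives a chromatic point whose angle is the hue, `H = atan2(y, x)` in
degrees with negative angles corrected by +360, and whose distance from
the origin, divided by 255, is the normalized saturation `S ∈ [0, 1]`.
Every neutral color (R = G = B) projects exactly onto the origin, so
whites, grays and blacks all have S = 0. Lightness is deliberately never
computed: the fingerprint is a pure chromaticity summary.

The **hue spectrum** of an image is a 360-bin histogram over integer hue
degrees that accumulates *saturation* rather than pixel counts: pixels
with `S > tv` (default threshold `tv = 0.05`) contribute their saturation
to the bin of their rounded hue, degree 0 folded into bin 360, and the
bins are divided by the number of contributing pixels. Two consequences
drive all uses of the method:

* approximately neutral backgrounds fall below the threshold and vanish
  from the spectrum — no segmentation step is needed;
* the count normalization makes spectra of different-sized images
  directly comparable, so color change over time shows up as displacement
  and reshaping of peaks.

Rounding of hue to integer degrees is half-away-from-zero, matching the
double→unsigned-integer conversion of the environment the algorithm was
originally published for. With one or zero above-threshold pixels the
spectrum is defined as all-zero rather than an error.

### Normalization divisor

Two conventions exist for the divisor: the count of above-threshold
pixels, and the total pixel count. They differ by the factor
`n_included / total_pixels` (the saturated-area fraction), which itself
carries information. The included-pixel count is the default
(`normalization="included"`); `normalization="total"` is available where
the saturated-area fraction should be retained in the bin magnitudes.

### Peaks

Peak characterization treats the spectrum as a circular signal (bin 360
is adjacent to bin 1). A peak is a strict local maximum — a plateau of
equal values counts once, located at its lowest degree — and its width is
the full width at half maximum obtained by linear interpolation on each
flank, with the flank search also circular and capped at half the circle
if the signal never drops below half height.

## PQS compression

The Polar Qualification System draws the spectrum as a polar figure
(vertex i at radius `V_i`, angle `i·α`, `α = 1°`) and compresses it to the
gravity point of that figure by triangular decomposition:

```
T     = ½ Σ V_i V_{i+1} sin α
PQS_x = 1/(6T) Σ [V_i cos(iα) + V_{i+1} cos((i+1)α)] · V_i V_{i+1} sin α
PQS_y = 1/(6T) Σ [V_i sin(iα) + V_{i+1} sin((i+1)α)] · V_i V_{i+1} sin α
```

This is exactly the shoelace polygon centroid of the vertex loop, which
the tests exploit as an independent oracle. For the full spectrum the sum
closes cyclically (pair 360→1); the closed figure makes the point
covariant under rotations of the hue circle, i.e. a circular shift of the
spectrum by k bins rotates the point by k degrees. For a *cropped* hue
range the fan is left open: only consecutive pairs wholly inside the
range contribute, α stays 1°, and no rescaling of the range onto the full
circle is attempted (rescaling would be a second, different statistic and
is left as future work). A figure with zero total area (no two adjacent
non-zero bins) has no gravity point and raises a dedicated error, which
the CLI surfaces as an explicit `NA` row.

## Chemometrics

Spectra are 360 collinear predictors, the classic PLS setting. `fit_plsr`
fits PLS1 (NIPALS, via scikit-learn, mean-centered, *not*
variance-scaled — bins share units) and reports R² and RMSE% on the
calibration set and on held-out samples. `fit_mvr` is ordinary least
squares with intercept on a small feature set — canonically the six RGB
summary statistics (channel means and population standard deviations) —
as the conventional baseline. Choices that were genuinely open:

* **RMSE%** is `100 · RMSE / |mean(measured)|`. Dividing by per-sample
  values would blow up near zero; the mean keeps the metric a stable
  relative error. A zero mean is an error.
* **Validation split**: fixed-seed random 70/30 by default, with
  leave-one-out and caller-supplied masks as alternatives. The split
  descriptor and seed are recorded in every report.
* **Component count**: when not given, the count minimizing leave-one-out
  RMSE on the calibration set, capped at 10. The cap keeps automatic
  selection in the regime PLS is for; callers may pass any count up to
  the predictor rank explicitly (e.g. full rank, where PLS1 reproduces
  OLS — a property the tests check to 1e-6).

Degenerate inputs fail loudly: requested components above the centered
predictor rank name the constant columns involved; a singular MVR design
is rejected rather than pseudo-inverted.

## Synthetic data

The generator renders what the method is designed for: colored objects on
approximately neutral backgrounds.

* `render_scene` rasterizes disks/rectangles (later object wins overlaps)
  with hard edges — no anti-aliasing — so included-pixel counts are exact
  integers, and `expected_spectrum` can compute the ground-truth spectrum
  per flat color instead of per pixel. Optional pixel noise is i.i.d.
  Gaussian per channel, clipped to [0, 255]: a threshold-robustness
  probe, not a camera model.
* `ripening_series` renders a disk whose nominal hue moves linearly from
  green (120°) to red (0°, bin 360) while saturation rises 0.45 → 0.85 —
  dull unripe green to strongly saturated red, kept inside the chroma
  hexagon (maximum normalized chroma away from the six cube corners is
  √3/2 ≈ 0.866, so saturations above that are unreachable at most hues).
  Hue varies across the disk face following a symmetric triangular
  distribution of half-width 8° around the nominal hue, with the central
  15% of the face exactly at the modal color. This emulates the mottling
  of real fruit and serves two testability ends: the modal bin dominates
  its neighbors by a wide margin, so the detected peak sits on the
  recorded ground-truth bin even after 8-bit quantization, and peaks have
  finite width and overlap between consecutive steps, so held-out samples
  share spectral support with calibration samples.
* `synthetic_regression_set` pairs the series' spectra with a response
  equal to the ripeness index t ∈ [0, 1] plus Gaussian noise, so a noise
  σ of 0.01 is 1% of the response range. The clean ripeness vector is
  returned alongside for recovery tests.

What the generator does **not** emulate: illumination gradients and color
temperature, specular highlights, shadows, camera gamma and white-balance
errors, demosaicing artifacts, and shading of curved surfaces. Passing
tests therefore demonstrate the correctness of the arithmetic and the
internal consistency of the method — not field performance on real
produce photographs, which additionally depends on standardized capture
conditions.

Problem sizes used in the test suite and the acceptance script — 64×64
images, series of up to 60 steps, 50–100 random replicates per oracle
comparison — were chosen as the smallest sizes at which every property
under test is exercised away from its degenerate corners.

## Numerical choices

* All arithmetic in double precision; integer channels widened before
  subtraction. 16-bit/channel inputs are rejected unless the caller
  explicitly opts into rescaling.
* Hue at the chromatic origin is defined as 0°; such pixels have
  saturation 0 and never pass the threshold, so the choice is
  unobservable downstream.
* The saturation threshold uses strict inequality (`S > tv`).
* Spectrum CSVs are written with 17 significant digits and parsed in
  round-trip mode, so write→read is bit-exact.
* Zero-radius PQS vertices contribute zero-area triangles naturally; no
  special-casing.

## Known limitations

* Hue/saturation here are computed from raw RGB intensities and differ
  from CIE L\*a\*b\* hue/chroma; no color management is applied.
* The cropped-range PQS convention (open fan, unchanged α) is one of
  several defensible definitions; points computed under different
  conventions are not comparable.
* Automatic PLS component selection by leave-one-out is biased optimistic
  when the same data are reused for validation; the random-split report
  is the honest generalization estimate.
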