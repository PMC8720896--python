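# huespectra

Color fingerprinting of fruit and vegetable images for postharvest
quality analysis.

Plant pigments — chlorophylls, carotenoids, flavonoids, betalains —
change during ripening and storage, so surface color is a primary quality
indicator for produce. `huespectra` summarizes the color of a whole image
as a **hue spectrum**: a 360-bin histogram of hue angle that accumulates
pixel *saturation* instead of pixel counts. Because white, gray and black
backgrounds have near-zero saturation, they disappear below a small
threshold without any segmentation step, and the saturated colors of the
produce stand out as peaks whose location, height and width track
ripening.

The package is aimed at machine-vision and postharvest researchers who
photograph samples on a neutral background and want a compact, size- and
background-invariant color feature for monitoring or chemometrics.

## The model

For each pixel, RGB is projected onto the chromatic plane

```
x = R − (G + B)/2          y = (√3/2)(G − B)
H = atan2(y, x)  (degrees, corrected into [0, 360))
S = √(x² + y²) / 255       (0 for neutrals, 1 at the six cube corners)
```

Pixels with `S > tv` (default `tv = 0.05`) add their saturation to the
bin of their rounded hue degree (0 folded to 360); bins are divided by
the included-pixel count, making spectra comparable across image sizes.

Two downstream analyses are built in:

* **PQS** (Polar Qualification System): the spectrum drawn as a polar
  figure is compressed to the gravity point `(PQSx, PQSy)` of that figure
  via triangular decomposition,
  `T = ½ Σ V_i V_{i+1} sin α` with `α = 1°` — a single 2-D point per
  image, optionally restricted to a hue range of interest.
* **Chemometrics**: PLS1 regression from the 360 collinear bins to a
  quality parameter (soluble solids, firmness, …), reported with R² and
  RMSE% against an ordinary multivariate regression baseline on RGB
  channel means and standard deviations.

A deterministic synthetic-scene generator (colored disks on neutral
backgrounds, a green→red ripening series with known ground truth)
supports testing and experimentation without any image downloads.

## Worked example

```python
from huespectra import (compute_hue_spectrum, find_peaks, pqs_point,
                        ripening_series, synthetic_regression_set, fit_plsr)

img, info = ripening_series(5, seed=0)[0]   # unripe: green disk on white
spec = compute_hue_spectrum(img)            # tv = 0.05
print(spec.n_included, spec.total_pixels)   # 1793 4096

best = max(find_peaks(spec, min_height=0.01), key=lambda p: p.height)
print(best.location, round(best.height, 4), round(best.width, 2))
# 120 0.0696 7.12

pt = pqs_point(spec)
print(round(pt.x, 4), round(pt.y, 4))       # -0.0144 0.0249

data, _ = synthetic_regression_set(n_samples=60, noise_sigma=0.01, seed=1)
model, report = fit_plsr(data)
print(round(report.r2_validation, 3), round(report.rmse_pct_validation, 2))
# 0.996 3.6
```

Reading the numbers: of the 4096 pixels only the 1793 disk pixels exceed
the saturation threshold — the white background contributes nothing. The
dominant spectral peak sits at hue 120° (green) with height ≈ 0.07 (mean
contributed saturation) and a full width at half maximum of ≈ 7°, the
mottling width of the synthetic fruit face. The PQS point lies up-left of
the origin, the direction of the green peak on the polar plot. A PLS
regression from the spectra of a 60-step ripening series recovers the
ripeness index on held-out samples with R² ≈ 0.996 and a relative error
of ≈ 3.6%.

## Command line

```
huespec spectrum IMG1.png IMG2.png --threshold 0.05 --out results/
huespec pqs results/spectra.csv --range 330:30 --out pqs.csv
huespec fit dataset.csv --method plsr --seed 0 --out report.json
huespec fixtures --n-steps 10 --out fixtures/
```

`spectrum` writes one `degree,value` CSV (plus JSON metadata sidecar) per
image and a combined `id × 360` matrix; `pqs` compresses each matrix row
to a gravity point, honoring wrapped hue ranges such as `330:30` for red;
`fit` produces a JSON report with calibration/validation R² and RMSE%;
`fixtures` renders the synthetic ripening series with ground-truth
sidecars. Exit codes: 0 success, 1 hard failure, 2 partial (some inputs
skipped).

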