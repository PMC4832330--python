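# mitofrac

Fractal morphometry of mitochondrial networks and tissue images, with the
downstream analyses that connect morphology to drug sensitivity.

Mitochondria form dynamic networks whose shape — elongated and reticulated
through the cytoplasm, or fragmented and condensed around the nucleus —
reflects the balance of fission and fusion and tracks disease state in
malignancies such as mesothelioma. Simple length/volume metrics miss this
structure, and visual classification is subjective. `mitofrac` implements
the two scale-resolved statistics that quantify it objectively:

- **Box-counting fractal dimension** *D*: tile the image with boxes of
  side ε over a ladder of scales and several grid positions; with N(ε)
  the occupied-box count (binary mode) or the summed per-box intensity
  range + 1 (grayscale differential mode), each grid gives
  D = −slope of the OLS fit of ln N(ε) on ln ε, and D is averaged over
  grids. Default protocol: box sizes from 2 px up to 45% of the shorter
  side, geometric ladder (ratio 1.3), 12 grid positions.
- **Gliding-grid lacunarity** λ: the squared coefficient of variation
  (σ/μ)² of per-box foreground-pixel mass, averaged over scales and grid
  positions. λ measures gappiness: 0 for translation-uniform mass, large
  for clumped, hole-ridden patterns.

High D / low λ characterises space-filling reticulated networks (and
malignant tissue architecture); low D / high λ characterises fragmented,
perinuclear phenotypes. Around this core the package provides image
preparation (max projection, constant background subtraction, ROI
masking, binarisation), four-parameter-logistic EC50 fitting of
cytotoxicity plates, mitochondrial stress-test metrics (basal/maximal
OCR, reserve capacity, OCR/ECAR ratio), empirical ROC analysis, Pearson
correlation panels, and a synthetic-data module (fractals of known
dimension, mitochondrial-network images, plates, flux traces, cohorts,
multi-line panels) so the entire pipeline is testable without external
data. See `docs/methods.md` for the full model description.

## Worked example

```python
import dataclasses
import mitofrac as mf

# 1. Validate the estimator on an exact fractal: level-4 Sierpinski carpet
carpet = mf.generate_sierpinski_carpet(4)
cfg = mf.BoxCountConfig(n_grids=1, count_mode="binary", scales=(1, 3, 9, 27))
est = mf.estimate_fd(mf.scan(carpet, cfg))
print(f"Sierpinski FD: {est.dimension:.6f}")        # analytic: log 8 / log 3

# 2. Profile two synthetic mitochondrial phenotypes
box = mf.BoxCountConfig(count_mode="binary", seed=0)
for name, preset in [("elongated", mf.synthgen.ELONGATED_RETICULATED),
                     ("fragmented", mf.synthgen.FRAGMENTED_PERINUCLEAR)]:
    img = mf.generate_mito_image(dataclasses.replace(preset, seed=0))
    prof = mf.profile_image(mf.subtract_background(img, 1000), box)
    print(f"{name}: FD = {prof.fd:.3f}  lacunarity = {prof.lacunarity:.3f}")

# 3. Fit an EC50 from a simulated cytotoxicity plate
plate = mf.generate_dose_response(
    mf.DoseResponsePlateParams(true_ec50=15.0, hill=1.2, noise_sd=3.0, seed=4))
fit = mf.fit_plate(plate)["compound"]
print(f"EC50 = {fit.ec50:.2f} (x/ {fit.se_ec50_multiplicative:.3f})")
```

Output:

```
Sierpinski FD: 1.892789
elongated: FD = 1.669  lacunarity = 1.415
fragmented: FD = 1.496  lacunarity = 7.601
EC50 = 14.59 (x/ 1.046)
```

The carpet's dimension is recovered to machine precision (the four
log–log points are exactly collinear). The elongated network scores a
higher fractal dimension and far lower lacunarity than the fragmented
perinuclear one — the ordering that separates control from diseased
phenotypes. The plate fit recovers the true EC50 (15.0) within its
multiplicative standard error.

The full pipeline — cell-line panel generation, batch profiling, EC50
fitting, flux-trace reduction, correlation and ROC reports — runs as

```sh
mitofrac run --synthetic --seed 1 --n-lines 8 --n-cells 40 --out study_out
```

writing `profiles.csv`, `panel.csv`, `correlations.csv`, `roc.json` and
`study.json` (all outputs embed the seed and a config hash; reruns are
byte-identical). Individual stages are available as `mitofrac synth`,
`prep`, `profile`, `ec50`, `stress`, `roc` and `correlate`.

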