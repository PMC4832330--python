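# Methods

## The morphometry model

`mitofrac` quantifies the spatial organisation of a grayscale microscopy
image with two scale-resolved statistics computed from one family of box
scans.

**Box scans.** An image (optionally restricted to a region-of-interest
mask) is tiled with square boxes of side ε for a ladder of box sizes and
for several translated grid positions. The ladder is geometric,
ε_{k+1} = round(ε_k · ratio) with ratio 1.3 by default, from 2 px up to
45% of the shorter side of the analysed region; a geometric ladder spaces
the points near-uniformly in log ε, which stabilises the regression below.
Twelve grid positions are used by default: grid 0 anchored at the origin
of the mask's bounding box, the others at seeded uniform offsets applied
modulo ε. Each grid tiles forward from its anchor; partial boxes at the
far edges are kept (they are real image area), while the thin strip before
the anchor lies outside that grid position. We do not extend grids
backwards with a second partial box per axis: doing so systematically
inflates the box count at scales comparable to the image and biases the
dimension estimate low (on the level-4 Sierpinski carpet the 12-grid mean
drops from 1.863 to ≈1.72 against the analytic 1.8928). Anchoring at the
mask bounding box makes the profile of a masked image exactly equal to the
profile of the image cropped to that rectangle.

**Fractal dimension.** Per box the scan records either occupancy (binary
mode) or the differential term δ = (max − min intensity among in-mask
pixels) + 1 (grayscale mode); the +1 keeps flat but occupied boxes
contributing one unit so N(ε) never vanishes on a nonempty region. With
N(ε) the occupied-box count (binary) or Σδ (grayscale), each grid yields a
dimension estimate D_g = −slope of the ordinary least-squares fit of
ln N(ε) on ln ε, and the reported dimension is the mean of the D_g (grids
contributing fewer than three usable scales are excluded and reported).
The sign convention makes a filled square score exactly 2 and an isolated
pixel exactly 0; grayscale-differential values may exceed 2 (up to 3 for a
maximally rough intensity surface).

**Lacunarity.** Per (grid, ε) cell, λ = (σ/μ)² over the per-box counts of
positive pixels — the squared coefficient of variation of box mass, with
population variance, over all boxes that intersect the mask (empty
in-mask boxes count; they are the gaps being measured). Cells with zero
mean mass are excluded and flagged. The summary is the mean of λ over all
defined (grid, ε) cells; a grid-averaged per-scale reduction is also
exposed (`LacunarityEstimate.by_scale`). λ = 0 for translation-uniform
mass and grows with clumping.

**Which count mode for which image.** Both modes run on any image. The
grayscale-differential mode is the default and suits continuous-tone
texture (e.g. scanned histology converted to luminance grayscale). For
fluorescence images of mitochondrial networks — background-subtracted to a
genuinely zero background, so that "positive pixel" is well defined — the
pipeline uses binary counting: there the object is a foreground set, and
occupancy scaling measures how the network fills the cytoplasm. In paired
synthetic experiments the binary dimension orders
elongated/reticulated above fragmented/perinuclear phenotypes in 50/50
seed pairs, while the differential dimension at the same contrast is
dominated by local intensity texture and orders them unreliably; both
modes remain available per image via `BoxCountConfig.count_mode`.

## Image preparation

Confocal z-stacks are reduced by maximum-intensity projection, then a
constant background (default 1000 intensity units, the value used with
16-bit confocal acquisitions of immunolabelled mitochondria) is
subtracted with clipping at zero. Clipping is deliberate: negative
intensities are meaningless as box masses, and a zero background makes
pixel positivity — the lacunarity mass criterion — exact. RGB histology is
converted to grayscale with Rec. 601 luminance weights. An `--invert`
option is provided for dark-on-light material; the package takes no
position on whether inversion is appropriate for a given stain. ROI masks
are boolean arrays; polygon-to-mask conversion is upstream tooling.

## Synthetic data: what it emulates, what it does not

The generator module replaces the study data (confocal stacks, tissue
microarray scans, raw plate fluorescence) with synthetic equivalents whose
ground truth is known:

- **Sierpinski carpet** (binary, exact dimension log 8 / log 3) and
  **fractional Brownian surfaces** (spectral synthesis: white noise
  filtered with amplitude ∝ f^−(H+1), theoretical surface dimension
  3 − H) validate the estimators analytically. Spectral synthesis was
  chosen over midpoint displacement for exact control of the Hurst
  exponent.
- **Mitochondrial networks** are persistent random walks (unit steps,
  turning angle ~ N(0, (1 − persistence)·π)) drawn as thick polylines,
  Gaussian-blurred with σ = width/2 to mimic the point-spread function,
  scaled to a peak intensity and offset by a constant detector background
  plus Gaussian noise. Default background 600 and noise σ 100 keep
  background + noise below the standard subtraction constant 1000, so the
  prepared image has a truly zero background. Two archetypes bracket the
  observed spectrum: *elongated/reticulated* (12 long, nearly straight
  tubules across the whole field) and *fragmented/perinuclear* (150 short
  fragments confined to a 12–40 px annulus around the centre of a 256 px
  field). Walks are kept inside the field or annulus by mirror-folding the
  offending coordinate — a reflecting boundary that vectorises cleanly.
  These are phenotype archetypes, not replicas of particular cell lines,
  for which no quantitative morphology parameters exist.
- **Dose-response plates** draw well signals from a four-parameter
  logistic viability curve times a vehicle signal, plus Gaussian noise;
  six replicates per concentration by default, mirroring a standard
  cytotoxicity design.
- **Stress-test traces** emit four measurement cycles per phase
  (baseline, oligomycin, FCCP, rotenone) with phase-typical OCR/ECAR
  levels.
- **Cell-line panels** draw a fragmentation level m ~ U(0,1) per line;
  morphology parameters interpolate continuously in m (tubules shorten
  and multiply, the admissible annulus shrinks from nearly the whole
  field to the tight perinuclear ring), and the true EC50 falls linearly
  from 70 to 7 concentration units in a driver that blends m with
  independent noise weighted by (1 − link_strength). At link 1 sensitivity
  is a deterministic function of morphology; at link 0 they are
  independent. The interpolation is continuous rather than a mode switch
  at m = 0.5 because a step morphology spectrum weakens the linear
  correlation the panel is designed to probe.

What the synthetic data does **not** model: optics beyond an isotropic
Gaussian blur (no depth attenuation, no anisotropic PSF), nuclei or other
organelles, multi-channel imaging, 3-D structure (networks are rendered in
2-D as a maximum projection would show them), plate edge effects, or
histology staining variation. Passing tests therefore demonstrate
correctness of the estimators and the internal consistency of the
morphology→sensitivity reasoning on images with known structure — not
performance on real micrographs.

## Dose-response fitting

Raw signals are normalised per compound to percent of the mean vehicle
(untreated) signal. The four-parameter logistic

y = bottom + (top − bottom) / (1 + 10^((log₁₀EC50 − log₁₀ dose)·hill))

is least-squares fitted over log₁₀ dose (Levenberg–Marquardt via
`scipy.optimize.curve_fit`), with vehicle wells excluded from the
regression (log 0 is undefined) but defining the 100% anchor.
Initialisation: top/bottom from the response extremes, log EC50 at the
dose nearest the midpoint, |hill| = 1 with sign from the response trend.
The bottom is unconstrained by default (over-toxicity overshoot is
allowed); `bounded=True` restricts it to ≥ 0. Flat responses (range below
a noise floor) and failed optimisations return a flagged fit with EC50 =
NaN — never zero. The standard error of log EC50 comes from the fit
covariance and is also reported as its back-transform 10^se, the
multiplicative "EC50 ± factor" style in which plate-fitting software
prints uncertainties; both interpretations are recorded because summary
tables in the field are ambiguous on this point.

## Downstream statistics

- **Stress-test metrics**: all rates are divided by protein per well;
  basal OCR/ECAR average the (four) baseline cycles rather than selecting
  one; maximal OCR is the largest FCCP-phase measurement only (the
  stress-test design defines the maximum against uncoupler stimulation,
  not a global max); reserve capacity = max − basal. The OCR/ECAR ratio
  (lower = more glycolytic) is computed per well and is
  protein-normalisation invariant.
- **ROC**: AUC is the normalised Mann–Whitney U statistic (ties count ½),
  which is exact under ties and directly checkable against pair counting;
  the curve enumerates all distinct thresholds. Orientation is explicit —
  for a disease-positive class the pipeline orients fractal dimension
  "lower" and lacunarity "higher", the direction in which malignant
  tissue departs from benign.
- **Pearson correlation** uses the exact-t two-sided p-value,
  t = r√(n−2)/√(1−r²); a seeded permutation option exists for small-n
  robustness checks. The correlation panel crosses every morphology and
  bioenergetic metric with every per-compound EC50 column, dropping pairs
  pairwise-complete; undefined cells are reported as missing, never as
  zero. No multiple-testing correction is applied across the panel.

## Numerical choices and degenerate inputs

- Scales with zero valid boxes are dropped per grid; a grid with fewer
  than three usable scales is excluded from the dimension mean and listed
  in `excluded_grids`; if no grid survives, estimation raises.
- All-zero images (no positive in-mask pixel) raise a degenerate-input
  error at scan time in both modes.
- Population (not sample) variance in λ: lacunarity is a moment ratio of
  the box-mass distribution, the standard gliding-box convention.
- Lacunarity cells with μ = 0 are excluded and flagged rather than set
  to 0 or ∞.
- Explicit `scales` overrides are accepted verbatim (used for analytic
  fixtures whose self-similar scales are known).
- Every stochastic component takes one explicit integer seed; there is no
  global RNG state, and identical (inputs, config, seed) reproduce
  byte-identical pipeline outputs.

## Problem sizes used in tests and the acceptance script

Analytic fixtures use the level-4 (81×81) carpet and 257×257 Brownian
surfaces. Phenotype comparisons use 256 px fields; panel studies use 8
lines × 40 cells at 128 px (linked) and 50 lines × 3 cells at 96 px
(decoupled null), with Monte-Carlo plate counts of 300–500. These sizes
were chosen so the full study runs comfortably on a single CPU while
leaving the measured quantities (ordering fractions, correlation signs,
recovery errors) well away from their decision boundaries.

## Known limitations

- The grayscale-differential dimension depends on the intensity scale of
  the input; images should be compared only under a common normalisation.
- Lacunarity at scales that do not divide the region mixes box sizes at
  the far edges, mildly inflating λ there; comparisons across images with
  a common config are unaffected, but absolute λ values at a single scale
  should use dividing scales.
- The box-size cap "45% of the shorter side" is an interpretation of a
  protocol stated in terms of image *area*; a 45%-of-area box would not
  fit non-square regions.
- No 3-D box counting, multifractal spectra, or per-pixel sliding-box
  lacunarity maps.
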