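# Methods

## Scope and data model

`canopyx` analyses replicated field trials in which each plot is observed
by three sensor channels — an RGB photograph, an 11-band reflectance
stack, and a thermal raster — alongside harvest measurements (grain
yield GY, thousand-grain weight TGW, grain number NG) and an N
fertilisation schedule. All per-plot quantities meet in one index table
(one row per plot), which the statistics layer consumes.

## Colour models

RGB images are assumed sRGB/D65, the working space consumer cameras
encode; no ICC handling is attempted. Three transforms are implemented:

* **HSI** — intensity I = (R+G+B)/3 on unit-normalised channels,
  saturation S = 1 − min/I, hue from the arccos chromaticity formula
  (red 0°, green 120°, blue 240°). Achromatic pixels get hue 0° and are
  excluded from vegetation windows, so the transform is total and
  NaN-free.
* **CIE-Lab / CIE-Luv** — sRGB piecewise gamma expansion, then an
  RGB→XYZ matrix derived at import from the sRGB primaries'
  chromaticities scaled to D65. Deriving the matrix (rather than typing
  a rounded one) makes greys land exactly on the achromatic axis
  (a\*=b\*=u\*=v\*=0 to machine precision), which downstream tests rely
  on. Published rounded matrices differ from this one by ~1e-7 per
  entry (~1e-3 in Lab units).

## Green-area classification

GA counts pixels with hue in [60°, 180°], GGA in [80°, 180°]; the nested
windows guarantee GGA ≤ GA by construction. Pixels with saturation
below 0.02 are never counted — hue is numerically meaningless near the
grey axis. CSI = 100(GA−GGA)/GA is defined as 0 at GA = 0 so bare-soil
plots do not inject NaNs into trial statistics; CSI is computed per plot
and averaged across plots (recomputing it from pooled GA/GGA means is
only approximate because the ratio does not commute with averaging).

## Spectral indices

Per-plot index = formula applied to the per-plot *mean* band reflectance
(means first, then formula), matching per-plot export workflows; a
pixelwise path exists for sensitivity work by passing unreduced rasters.
The additive constants (SAVI L = 0.5, EVI +1, OSAVI +0.16) are applied
on whatever numeric scale the stack declares (`unit` [0,1] or `8bit`
[0,255]); the package never rescales silently because those constants
are scale-dependent — NDVI/PRI/WBI are invariant to a global scale
factor, SAVI/EVI/MCARI/OSAVI are not, and both behaviours are tested.
The twin 780 nm filters are averaged on read; 720/860 nm bands are
carried through I/O but enter no formula (OSAVI uses 780 nm, the other
NIR formulas 840 nm, as each formula names). Zero denominators yield a
flagged NaN plus a per-plot warning record, never a silent infinity.

Thermal rasters are 16-bit raw counts converted as °C = counts × s −
273.15 with s the K-per-count scale. The default s = 0.01 (centi-Kelvin)
is a documented assumption — a literal "Kelvin × 10 000" cannot fit a
16-bit integer — and is config-exposed. Values outside −100…150 °C
raise a plausibility warning, the usual symptom of a wrong scale.
Summaries are the arithmetic mean and *population* sd over unmasked
pixels.

## Plot extraction

Pixel coordinates are 0-based with rows increasing downward; a pixel
belongs to a polygon when its centre (col+0.5, row+0.5) is inside.
Polygons half-open on the right/bottom edge tile a mosaic without double
counting (tested). Geo-coordinates require an explicit affine transform
mapping pixel→world; extraction refuses to guess a registration. The
inward buffer (default 0) erodes polygons before cutting, for trimming
mixed border/alley pixels; whether to trim is left to the user since
plot-edge handling is a trial-specific choice.

## Nitrogen use efficiency

aNUE = (GY − GY₀)/N and NPFP = GY/N with GY₀ the genotype-specific mean
of the zero-N control plots — the control is the reference point, so a
genotype's unfertilised performance weighs on all its aNUE values. With
yields and N both in kg/ha the metrics are g grain per g N directly.
Both are flagged NaN at N = 0. The algebraic identity NPFP − aNUE =
GY₀/N inverts any published (aNUE, NPFP) pair to the control yield it
implies; the consistency checker computes this per fertilised row,
requires the per-genotype coefficient of variation to stay below 0.5%,
and re-predicts every printed NPFP cell from the mean baseline with a
±0.02 rounding allowance (inputs printed to two decimals propagate
about that much). Yield components are linked by GY[kg/ha] =
NG[m⁻²] × TGW[g] / 100.

## Trial statistics

* **ANOVA/Tukey** — one-way F-test plus Tukey HSD pairwise comparisons
  (Tukey–Kramer on unbalanced data); the compact letter display is built
  by insert-and-absorb so that two levels share a letter *iff* their
  pair is not rejected — the relation is checked against the rejection
  matrix directly, guarding against transitivity bugs. Levels with <2
  observations are excluded with a warning; all-constant groups take an
  exact-separation fast path.
* **PCA** — correlation-matrix PCA via SVD of the standardised data;
  constant traits are dropped with a warning; within each component the
  largest-magnitude loading is made positive so signs are reproducible.
* **Correlation network** — pairwise Pearson r with the exact
  two-sided t-transform p-value (n−2 df), edges requiring |r| > 0.6 and
  p < 0.001, both thresholds configurable, p uncorrected (the
  conventional display choice for such networks).
* **Stepwise OLS** — forward and backward selection under AIC (default)
  or p-enter/p-remove. With `direction="both"` the two runs are
  independent; the forward result is reported and any disagreement is
  attached to the results, never silently resolved. Ties break
  lexicographically on predictor name, making selection deterministic.
  Collinear candidates are skipped with a warning.
* **LMG variance shares** — each predictor's incremental R² averaged
  over all orderings, computed exactly via the subset-weighted form
  (2^p subset fits); shares are non-negative and sum to the model R².
  Exact enumeration is refused above 12 predictors unless Monte-Carlo
  ordering sampling is requested.
* **SEP** — the residual standard error √(RSS/(n−p−1)); this definition
  is stated explicitly because "standard error of prediction" is used
  loosely in the field.

## Synthetic trial generator

The generator emulates a barley N-response trial: 3 genotypes (one
conventional, two hybrids) × 10 treatments × 3 replicate blocks = 90
plots, reusing the ten published split-application N schedules (four
dated doses summing to 0–170 kg/ha).

Per-plot truth: green cover ≈ 0.40 on unfertilised plots and 0.78–0.84
on fertilised ones (rising mildly with total N), genotype offsets of
−0.06/+0.02/+0.03, and a ±0.05 uniform wobble for field heterogeneity —
levels chosen to match the canopy closure of a booting-stage trial.
The senescent share of the non-green area is drawn independently
(15–45%), so total vegetated area is not a deterministic function of
green cover. Yields follow GY(t/ha) = 1.41 + 6.46 × green_cover +
N(0, 0.45); intercept and slope are the scale of a ground green-area
yield model for such trials, and the 0.45 t/ha noise puts the
recoverable r² near 0.75–0.80, the regime such models operate in. TGW
is a genotype constant plus wobble and NG is derived so GY = NG×TGW/100
holds exactly.

Artifacts per plot:

* **RGB image** (64×64): pixel class counts allocated by
  largest-remainder rounding (deterministic — only placement and jitter
  are random), hues at 110° (green), 70° (senescent), 30° (soil) with
  4° per-pixel jitter, plus a 3° sd per-photo global hue shift
  (white-balance wobble) and per-photo saturation/brightness jitter
  (0.05 sd around 0.6/0.8, constant *within* an image so classification
  stays a pure function of hue). The windows place the three centres
  cleanly in GGA / GA-only / neither, so with all jitters set to 0 the
  classifier recovers the configured fractions to 1/n_pixels exactly —
  the generator's central oracle.
* **Reflectance stack**: per band, the cover-weighted average of three
  endmember spectra (green canopy, senescent tissue, soil; typical
  shapes with red absorption and NIR plateau for green canopy), plus a
  per-plot per-band calibration offset (sd 0.01 reflectance) and
  optional per-pixel noise. The plot-level offset models the dominant
  real error source — residual reflectance calibration and illumination
  — which does not average out over a plot.
* **Thermal raster**: canopy pixels (green+senescent cover) at the
  canopy temperature, soil pixels warmer, per acquisition
  (morning/afternoon), with 0.3 °C pixel noise; with noise off the
  raster mean is the cover-weighted mixture mean exactly.

One RNG per artifact is derived from (master seed, plot index, stream),
so a single plot regenerates identically without global state, and a
fixed config+seed reproduces every file byte-identically (tested by
hashing).

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: within-plot spatial structure
(pixels are exchangeable; real senescence patches and row structure are
absent), shadows and specular highlights, BRDF/illumination geometry,
atmospheric effects, camera optics, or genotype×treatment interaction
in yields (the generative yield model is purely additive in cover).
Recovery results on synthetic trials validate the *computational
pipeline*, not the field performance of any index.

### Measurement error in competitor channels

With a noiseless generator every index is a deterministic function of
the same latent cover fractions, and "which proxy does stepwise
selection keep" degenerates into numerical coin-flipping among
near-duplicates. The default calibration/white-balance/exposure noise
terms above give the non-RGB channels the error structure real
acquisitions have, which is what makes the stepwise-recovery check a
meaningful statement: GGA, the direct pixel-count measure of the
generative variable, is kept in ≥99/100 seeded trials.

## Numerical choices and degenerate inputs

* Hue wraps modulo 360; achromatic hue is 0° by convention.
* CSI(GA=0) = 0, flagged per plot rather than NaN.
* Zero spectral denominators → NaN + warning record.
* Fractions must sum to 1 within 1e-9; class counts by largest
  remainder with ties broken by largest fractional part.
* Tukey letters are assigned in order of first appearance of each
  level, making the display stable across runs.
* All acceptance-grade comparisons in the test suite use the oracle's
  own tolerance: 1e-12 for retyped scalar formulas, 1e-3 for colour
  conversions against independently derived constants, 1/n_pixels for
  fraction recovery, ±0.02 for values reconstructed from numbers
  printed to two decimals.

## Known limitations

* The HSI hue used for classification is the arccos form; hexcone (HSV)
  hue differs by up to ~1° away from the primaries. Window edges are
  far from class centres, so this does not move classifications, but
  windows tuned for HSV software should be re-checked.
* Geo-mode extraction supports affine registrations only (no CRS
  reprojection).
* LMG sampling mode (for >12 predictors) is Monte-Carlo and returns
  shares with simulation error; exact mode is the default elsewhere.
* The published-grid consistency check can validate a printed NUE table
  against its own definitions but cannot detect errors that shift aNUE
  and NPFP consistently.
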