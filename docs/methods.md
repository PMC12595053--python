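# Methods

## Scope and model

`ensotel` implements a correlation-based teleconnection analysis between a
monthly ocean index (ONI-like: a 3-month running mean of sea-surface
temperature anomalies with ±0.5 °C phase thresholds) and monthly gridded
terrestrial fields, followed by two aggregation products: an entropy-weighted
climatic exposure index and a sun/shade productivity sensitivity typology,
plus a lagged-response timing analysis.  The statistical model is
deliberately minimal: each pixel's anomaly series is treated as an
independent linear-plus-noise responder to the index, and all inference is
per-pixel Pearson correlation with a two-sided t-test at p < 0.05.  No
spatial dependence, field significance, or multiple-testing correction is
modelled, matching the per-pixel mapping rule the pipeline implements.

## Processing chain and conventions

* **Phase labels.** After the 3-month running mean, months with value
  ≥ +0.5 °C are El Niño, ≤ −0.5 °C La Niña, else neutral.  The boundary is
  inclusive; "exceeding ±0.5 °C" is ambiguous at equality, so the choice is
  explicit and the threshold configurable.  Phase filtering of data uses
  these per-month labels; the 5-month episode catalogue
  (`extract_episodes`) is reporting convenience only.
* **Running mean edges.** The centered 3-month mean keeps series length by
  using the available 2-month window at the first and last months.  This
  keeps a 348-month index aligned month-for-month with 348-layer cubes,
  at the cost of slightly noisier endpoints.
* **Cube preprocessing order** is fixed: calendar-month anomalies → per-pixel
  OLS detrend → 3-month smoothing, enforced by provenance flags
  (`anomalized/detrended/smoothed`); calling stages out of order raises.
  "Subtracting the period mean" is read as the per-calendar-month
  climatological mean (the standard anomaly definition for monthly data); a
  single-overall-mean switch exists because the coarser reading is also
  defensible.
* **The index is not anomalized or detrended by default** — it is already an
  anomaly series maintained against an updating baseline.
  `preprocess_index` applies the full cube treatment to the index for users
  who want strict symmetry (and for noise-free proportionality checks, where
  r = ±1 only holds under identical treatment of both sides).
* **Lag convention.** Positive lag means the field responds after the index:
  the correlation pairs index month t with field month t + lag.  Used
  identically in the generator and the analysis.
* **Missing data** propagate: climatology is missing-aware, detrending needs
  ≥ 3 valid months per pixel, and a smoothed value is missing when any
  window member is missing.
* **Grids** are north-up, pixel-center registered; cubes and masks must share
  registration exactly (checked, never resampled — the only resampling in
  the package is the fine→coarse forest-loss aggregation).

## Correlation statistics

Per pixel, the sample Pearson r over the phase months gets a two-sided
p-value from t = r·√((n−2)/(1−r²)).  Defaults: min_n = 8 complete pairs for
a defined correlation (the t transform needs n > 2; 8 additionally guards
absurd small-sample fits), α = 0.05 strict.  Inputs that are constant up to
floating-point rounding (relative to the cube-wide data scale) are undefined
(NaN), not zero-correlated.

**Serial-correlation caveat.** The 3-month smoothing makes both series
MA(3)-autocorrelated; for two smoothed independent series the variance of
r̂ is inflated ≈ 2.1× (1 + 2·(2/3·2/3 + 1/3·1/3)), so the naive per-pixel
test rejects a true null at roughly 6–17 % instead of 5 % depending on how
many phase months are temporally adjacent.  The default pipeline applies no
correction, matching the mapping rule it implements; `use_neff=True` enables
a Bretherton-style lag-1 effective-sample-size correction (estimated from
consecutive-in-time sampled pairs only), which measurement shows slightly
over-corrects for an MA(3) process (~3 % rejection).  The package's null
calibration test therefore checks the regime where the t-test is exact —
unsmoothed white-noise fields against the smoothed index — and this caveat
is the main reason significance counts on real smoothed data should be read
qualitatively.

## Entropy Weight Method

With one row per variable over the n retained pixels, X_ij = |r_ij| where
variable i is significant at pixel j and 0 otherwise:
P_ij = X_ij/Σ_j X_ij, E_i = −(1/ln n)·Σ_j P_ij ln P_ij (0·ln 0 := 0),
d_i = 1 − E_i, w_i = d_i/Σ d_i, exp_j = Σ_i w_i·Xs_ij.

Decisions taken where the procedure is underdetermined:

* **Retention rule.** A pixel enters the EWM domain if at least one of the
  variables is significant there (union); non-significant entries contribute
  X_ij = 0.  "Only pixels with significant correlations were retained" does
  not state an all-variables intersection, and the union keeps the domain
  non-degenerate while zeros encode absent stress.  `retention=
  "intersection"` is available.
* **Scaling of the final index.** The weighted sum uses |r| min–max scaled
  to [0, 1] per variable over the domain, so exp_j itself lies in [0, 1] as
  the exposure index is described.  Using raw |r| or the normalized shares
  P would change only the scale, not the ordering, of exp_j; the choice is
  flagged here because the formula as stated (Σ w_i X_ij) does not pin down
  X's scaling.
* **Stress directionality** (sign of r, with the La Niña sign flipped so +1
  is always the warm-phase stress side) is carried as a separate integer
  table for map colouring and is not multiplied into the index magnitude —
  mixing signs into the entropy computation would make P_ij negative and
  the entropy undefined.
* An all-zero variable row (no significant pixel anywhere) is dropped with a
  warning and weight 0; all-uniform variables (every E_i = 1) are an error
  ("no information") with guidance.
* The sklearn wrapper (`EntropyWeightModel`) is the same computation with
  samples = pixels and features = variables; `fit` learns weights and the
  min–max ranges, `transform` applies them to (possibly new) pixels, clipped
  into [0, 1].

## Sensitivity typology

Significant GPP correlations become directions: sign(r) under El Niño,
−sign(r) under La Niña (+1 = increased productivity under the phase's warm
extreme).  Categories: (+1, +1) both_increase; (−1, −1) both_decrease;
sun −1 with shade not −1 → sun_decrease_only; shade −1 with sun not −1 →
shade_decrease_only; everything else (including one-sided increases) is the
residual "none".  The one-sided *increase* combinations are deliberately not
their own class — the typology's named classes mirror the four mapped
response classes (joint responses and decrease-only contrasts).  Area
percentages use all masked pixels as the denominator, so the four named
classes need not sum to 100 %.

## Lag analysis

Profiles summarize all masked pixels with defined r (no significance filter)
per lag −3…+3 with median, quartiles, and Tukey whiskers.  The transition
detector returns the earliest consecutive pair whose medians differ in sign
(a change to or from exactly 0 counts); when no sign change exists it falls
back to the conventional (−1, 0) pair for comparability across layers.
Magnitude-only changes are not auto-detected — the pair can be chosen
manually.  The transition map classifies pixels non-significant at the
earlier and significant at the later lag by the later lag's direction.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
real geophysics: index x_t = a·x_{t−1} + ε_t (default a = 0.8,
σ_ε = 0.3 °C → stationary SD ≈ 0.5 °C), recentered to zero mean per
realization — emulating the index's updating anomaly baseline, and necessary
because a persistent uncentered AR(1) draw can leave one phase nearly empty,
which a baseline-maintained index cannot (measured across 300 seeds:
minimum 11, mean ≈ 46 months per phase over 348 months, comparable to the
real 1992–2020 record).  Fields are
climatology(month) + trend·t + β_ij·x_{t−lag_ij} + N(0, σ_n²), with the
climatology a fixed sinusoid (amplitude 1 by default) so the anomaly step is
non-trivial.  One root seed feeds deterministic per-component substreams
(index / each named cube / masks), so adding a variable never perturbs the
others.

The bundled scenario (`default_scenario`) uses a 40 × 40 grid × 348 months:
each climate variable carries |β| = 1 on a block covering 25–60 % of pixels
(VPD patchiest, hence the heaviest EWM weight by construction; temperature
and dryness respond positively, water variables negatively), and the GPP
pair plants the four typology categories in quadrants (both decrease / both
increase / opposite with canopy decreasing / opposite with subcanopy
decreasing) with the shade layer responding one month late.  Recovery tests
use β = 2 and σ_n = 0.25: within a phase the index is range-restricted
(SD ≈ 0.2 °C conditional on |value| ≥ 0.5), so those settings give a
theoretical in-phase r ≈ 0.85 and per-pixel p ≈ 10⁻⁴ even at the smallest
phase-month counts the generator produces, which is what "high
signal-to-noise" has to mean for ≥ 99 % recovery criteria.  The default
β = 1, σ_n = 0.5 setting (in-phase r ≈ 0.37) is kept as the realistic
low-power regime for the demo pipeline.

What the generator does *not* emulate: spatial covariance of fields, ENSO's
spectral peaks and seasonal phase-locking, trends in variance, or
non-Gaussian tails.  Passing tests therefore demonstrate correctness of the
statistical machinery on the assumed model, not skill on real satellite or
reanalysis data.

## Numerical choices

* Degenerate correlation inputs: undefined at variance ≤ n·(10⁻¹²·scale)²,
  with scale = the largest |value| in the correlation's data (cube-wide for
  maps), so exact-arithmetic residues of climatology subtraction do not
  produce spurious correlations.
* Entropy: 0·ln 0 := 0; k = 1/ln n requires n ≥ 2 pixels.
* EWM weight round-trips from a published table can disagree with the
  published weights by one unit in the last printed digit when the published
  weights were rounded from unrounded entropies; the bundled reference table
  has two such cells (its own weight columns do not all sum to 1 exactly).
* Episode extraction ties and boundaries: maximal runs, ≥ 5 months, runs at
  series edges included.
* Problem sizes in tests: 40 × 40 × 348 for calibration/recovery (seconds per
  map on one core), smaller grids for unit checks — large enough for the
  binomial bands and recovery fractions quoted, small enough that the whole
  suite stays interactive.

## Known limitations

* Naive p-values on doubly smoothed series are anticonservative (see above).
* No reprojection: all rasters must share a CRS and registration.
* The deforestation filter defaults to the conservative "any loss" rule and
  is applied to the GPP mask only (climate variables keep the suitability
  mask), mirroring the motivating workflow; both are configurable.
* NetCDF output uses the classic (NetCDF-3) format; TIFF outputs carry their
  georeferencing in a JSON sidecar rather than embedded GeoTIFF tags.
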