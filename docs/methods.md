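# Methods

## The phenomenon and the analysis model

Over a large, flat temperate forest the daytime boundary layer grows
faster and moistens earlier than over surrounding cropland (lower
albedo, higher roughness, sustained evapotranspiration). The
observable signature in geostationary imagery is a higher *cloud
frequency* — the fraction of valid daylight (06–18 UTC) 15-minute slots
in which a pixel is flagged cloudy — over forest in summer, an earlier
diurnal onset, a downwind-edge maximum under background wind
(forest-breeze convergence), and a step decrease when windthrow removes
the forest. `forestcloud` implements the full observational chain for
this signal and a synthetic scene generator that provides ground truth
for every stage.

## Synthetic scene generator

The generator produces, on an abstract north-up km grid (1 px = 1 km,
no map projection — geolocation is out of scope):

* **Clear-sky counts.** Per pixel and (dekad, hour) bin:
  `round(clear_base_counts × albedo × E(dekad, hour))`, where `E` is a
  smooth diurnal half-sine times a seasonal factor
  `0.55 + 0.45·cos(2π(doy − 172)/365.25)`. Counts rise with surface
  albedo, as a broadband visible channel does: forest (albedo drawn
  once from 0.11–0.14) is darker than cropland (0.16–0.19). The truth
  level is integer-valued and constant within a bin, so the climatology
  estimator has a well-defined target. `clear_base_counts = 1500` puts
  clear-sky counts in the 20–280 range of the 10-bit scale, leaving
  head-room for cloud brightening.
* **Cloud occurrence.** Independent Bernoulli per pixel and slot at
  `p_cloud_base = 0.3`, plus `delta_forest_jja = 0.10` over forest
  pixels during June–August (calendar months; zero otherwise). The
  default enhancement is the middle of the 0.05–0.15 range the summer
  forest contrast spans. With `diurnal_lead_hours = 0` the enhancement
  is flat across the daylight window; a positive lead applies a
  mean-preserving sinusoidal profile shifted earlier in the day
  (earlier onset over forest). Independence keeps binomial error bounds
  exact for tests; an autocorrelated synoptic day-state regime is
  deliberately *not* the default for that reason.
* **Downwind displacement.** Each day the enhancement field is shifted
  by whole pixels, `−round(coeff·v)` rows and `round(coeff·u)` columns
  (row 0 is north), with `coeff = 2 km/(m s⁻¹)`. A southerly wind thus
  moves the enhancement north — the simplest testable rendering of a
  downwind-edge maximum. The daily wind series is an input (CSV); when
  absent one is drawn (u ~ N(0.5, 2.0), v ~ N(0.5, 2.5) m s⁻¹, iid
  days, a mild south-westerly bias typical of the Atlantic coast).
* **Windthrow breakpoint.** After `klaus_date` the JJA enhancement
  inside the damage zone drops to `klaus_residual_delta = 0.020`.
* **Rendering.** `count = round(clear + 50·1[cloud] + N(0, 2))`,
  clipped to [0, 1023]; missing observations injected at a configurable
  rate and stored as −1. The 50-count cloud boost is a free parameter
  chosen to exceed the 10-count detection threshold comfortably; the
  generator warns if it does not.

All randomness flows from one integer seed through separate spawned
streams (static fields, wind, cloud draws, sensor noise), so truth and
counts are bit-reproducible and `render_counts` is deterministic given
the truth.

**What the generator does not emulate:** radiative transfer, spatially
correlated cloud fields, synoptic persistence, satellite viewing
geometry and calibration drift. Passing tests therefore demonstrate
the *statistical machinery* — estimator consistency, calibration of the
tests, recovery of imposed effects — not retrieval physics.

## Clear-sky climatology and cloud detection

Observations are pooled per pixel into (dekad, hour) bins: 36 ten-day
periods (the last absorbing days 351–365/366) × the daylight hours,
432 bins for the default 06–18 UTC window. The clear-sky count is the
centre of the steepest section of the bin's empirical CDF,
operationalised as the integer `v` maximising the number of samples in
`(v − w/2, v + w/2]` with `w = window_w = 3` counts; ties break toward
the smallest `v`, because clouds only brighten and the clear mode is
the darkest dense one. Bins with fewer than `min_samples = 20`
observations are invalid rather than extrapolated. A slot is *cloud*
when its count strictly exceeds climatology + 10 counts; "exceeds" is
implemented strictly so the decision boundary is bit-exact testable.

The estimator's failure mode is informative: when the per-bin cloud
fraction approaches 0.5 the cloudy mode can out-number the densest
clear window and the bin locks onto clear-sky + boost. At the default
conditions (30% contamination, 80 samples per bin from a 2-year
record) this affects well under 1% of bins; over enhanced forest in
summer (40% contamination) it reaches a few percent, which also
depresses the *detected* forest–non-forest contrast (≈0.07 for a
configured 0.10) while truth-mask statistics recover 0.10 exactly
within binomial error. A longer record shrinks the effect; it is a
property of mode estimation at p→0.5, not a bug.

## Frequency surfaces and box statistics

Frequency maps carry their integer cloudy/valid counts; fractions are
derived views. This makes aggregation identities exact: wind-class
composites recombine to the all-days map bit-for-bit by summing counts.
Missing flags drop out of numerator and denominator (frequency is
conditional on valid observation). Box series average the per-pixel
frequency over box pixels (the pooled-count alternative is a one-line
change via the stored counts); the non-forest reference weights its two
boxes equally per box. Dekadal box values pool each dekad's counts,
equivalent to slot-weighted means of the daily values.

Forest/non-forest comparisons use the Welch (unequal-variance) t-test
on daily values — the variant is unspecified in this kind of analysis;
Welch is robust to unequal box variances. Daily values are treated as
independent (no autocorrelation correction; with the iid generator this
is exact, for real data it would be anticonservative — a documented
limitation). Uncertainty on binned series comes from resampling
*days* with replacement (n_boot = 1000, seeded) and taking 50%/95%
percentile intervals of the bin means. Significance of the
forest-minus-non-forest difference resamples days jointly for both
boxes — preserving day-level synoptic correlation — and marks bins whose
95% difference interval excludes zero; interval non-overlap of the two
separate series is available as a conservative alternative
(`method="overlap"`).

## Wind composites

Days are classified by daily regional meridional wind with edges at
±1 m s⁻¹ (v < −1, −1 ≤ v ≤ 1, v > 1; a value on an edge joins the
central class) and into eight 45° direction sectors under the
meteorological convention (direction the wind blows *from*; sector
boundaries go to the lower sector). Per class, the frequency map over
that class's days gets its own 90th-percentile level (numpy linear
interpolation between order statistics, fixed for bit-exact tests) and
exceedance mask; per-class levels absorb differences in mean cloudiness
between wind regimes. The quantile domain excludes water pixels when a
land-cover map is supplied. The downwind test statistic is the
exceedance-mask centroid shift relative to the forest centroid along
the wind axis.

## Seasonal breakpoint model

The dekadal forest-minus-non-forest difference is fitted with

    d(t) = c + b·t + A·sin²(π(t − φ)),   t in decimal years,

an offset, linear trend, and fixed 1-year harmonic with amplitude
A ≥ 0 and phase φ ∈ [0, 1) (peak at φ + ½ mod 1; the default synthetic
phase 0.04 peaks in early July). This is the minimal
"squared sine with trend". Fitting is Levenberg–Marquardt least squares
with multi-start over φ ∈ {0, ¼, ½, ¾} (the sin² surface has phase
local minima); the winner is canonicalised via
`A·sin²(π(t−φ)) = −A·sin²(π(t−φ−½)) + A` and φ mod 1, with a refit from
the canonical point so the covariance matches the reported
parameterisation. Preconditions: ≥ 8 non-missing dekads spanning
≥ 0.95 years (one year of mid-dekad points spans 0.96). A constant
series returns A = 0, φ = 0 by convention. 95% CIs are asymptotic
(Jacobian covariance, t quantile with n − 4 df) by default; a
dekad-resampling percentile bootstrap is available. The storm
breakpoint is handled by two independent segment fits (the simplest
reading of a before/after contrast; a joint model with a single step in
A would share c, b, φ and is intentionally not the default), reporting
both amplitudes, their CIs, and the post/pre ratio.

At the study's effect sizes (A: 0.114 → 0.020, residual noise 0.02,
five years per segment) the recovery simulation shows ~95% CI coverage
of each amplitude and disjoint pre/post CIs in ~100% of replicates.

## Problem sizes used in tests and the acceptance script

Chosen as the smallest sizes at which the statistical claims are
well-resolved: detector fidelity on a 2-year, 120×120 km scene
(80 samples per climatology bin); enhancement recovery and type-I
calibration on 40×40 km scenes (the t-test calibration uses the
generator's truth masks — detector fidelity is established separately
and near-ceiling, so running the detector 1,000 times would only add
runtime); breakpoint recovery on 100 model-generated 10-year series.
The enhancement-recovery scene uses a calm wind series so the
displacement mechanism (tested on its own with a three-regime wind
input) does not move the signal off the small grid.

## Known limitations

* Spatially and temporally independent cloud draws overstate the
  effective sample size relative to real cloud fields; all calibration
  statements (type-I rate, CI coverage) are exact only under the
  generator.
* The clear-sky estimator degrades as per-bin cloud fraction
  approaches 0.5 (above); real overcast climates would need longer
  records or a more robust mode estimator.
* No multiple-testing correction across bins in the significance
  shading, matching the analysis it mirrors.
* The NetCDF writer targets the classic format (scipy backend);
  cloud-flag bytes are stored as 16-bit integers with the 0/1/255
  value convention.
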