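# Methods

## Model and estimator

The package parameterizes diurnal land-surface cooling with Newton's law:
after the early-afternoon temperature maximum, the surface temperature
relaxes exponentially toward an ambient temperature,
`T(t) = T_a + (T_0 - T_a) exp(-R_dk t)`. The decay constant R_dk carries
the vegetation signal through the thermal-mass relation
`R_dk = alpha_tot / (rho c (V/A))`: the printed units of the specific heat
in the source material are unconventional, so `c` is treated throughout as
an opaque positive factor and no unit algebra is enforced on the
`ThermalProperties` bundle.

The observable estimator uses one day and one night temperature,
`R_dk = ln(T_d/T_n) / Delta t`, with the natural logarithm (the estimator
must invert `exp(-R_dk t)`, so no other base is consistent) and Kelvin
temperatures (the ratio is not invariant under an offset; a property test
documents this). `Delta t` defaults to 12 h — both the Aqua
(13:30 → 01:30) and Terra (10:30 → 22:30) overpass pairs imply it — and is
configurable per dataset.

### Approximation bias

The estimator drops the ambient term of the exact solution,
`T(t)/T_0 = exp(-R_dk t) + (T_a/T_0)(1 - exp(-R_dk t))`, and is therefore
exact only in the limit `T_a -> 0`. For warm ambients the estimate is
biased low; `approximation_bias(state, dt)` returns the exact bias by
sampling the closed-form trajectory and applying the estimator. Two
consequences matter in practice and are verified by tests:

- the recovery error of the full pipeline on a simulated scene equals this
  closed-form bias pixel-by-pixel (to 1e-12), and
- sensitivity to the true k is attenuated by roughly
  `(T_peak - T_a) exp(-k dt) / T_n` (about 0.08 under the default warm
  scene), which is why the index is best read as a *relative/monotone*
  measure — rank order against the truth is preserved exactly in
  noiseless scenes — and why injected trends must be calibrated in the
  estimated-rate domain (below).

### Aggregation

Annual means average the per-pair estimates over valid pairs only; cloudy
and missing pairs are excluded, never zero-filled, and NaN is the single
missing-value sentinel everywhere. A finite annual value requires at
least `min_pairs` valid pairs (default 10 of the at-most-46 8-day
composites in a year; no published completeness rule exists, so the
default is deliberately permissive and always reported alongside a
per-pixel pair-count raster). Warm nights (T_n > T_d) produce negative
rates; they are returned as-is and flagged, with an optional mask-out
switch, since the source procedure excludes freezing and fire but is
silent on sign inversions. The diurnal temperature range
(DTR = T_d - T_n) is provided under the same averaging contract for
comparison studies.

## Synthetic scenes

`make_scene` emulates the study conditions: a smooth spatial vegetation
gradient mapped to true decay constants in 0.005–0.05 hr^-1 (dense
vegetation = small k) with the diurnal peak temperature co-varying
inversely (sparser = hotter, 305–320 K), nighttime ambient 285 K, peak at
13.5 h local, dawn fixed at 06:00, 46 composites per year over 15 years
(2003 start), additive Gaussian temperature noise (default experiments
use sigma = 1 K, the temperature-domain error scale of satellite LST),
and per-date independent Bernoulli cloud masking applied jointly to day
and night (pairs come from one composite). All randomness derives from a
single seed; identical seeds give byte-identical scenes on disk.

The heating branch (dawn to peak) is a half-sinusoid — a pluggable
stand-in, since only the cooling branch carries physical content. No
quantitative conclusion depends on its shape beyond the ordering property
it guarantees: a platform sampling nearer the peak and the nighttime
minimum (Aqua) yields decay rates at least as large as an
earlier-sampling platform (Terra) when the ambient is warm. Simulated
Terra-on-Aqua comparisons give RMA slopes well below 1 with Pearson r
above 0.99, qualitatively matching the cross-platform behavior of the
real index; the slope's numeric value depends on the stand-in heating
curve and the chosen ambient, so it is reported, not asserted.

### Calibrated strong trend

With the warm ambient, a trend injected into the true decay field reaches
the estimates attenuated by the factor above (~0.08). The simulator's
strong-trend constant (`CALIBRATED_TREND_SLOPE = 5e-4 hr^-1 yr^-1`) was
calibrated once by simulation so that the induced drift in the *estimated*
annual rates is about 0.5 of their year-to-year noise under the default
conditions (1 K noise, 30% cloud, 46 composites), which drives
Mann-Kendall detection at p < 0.05 on essentially every pixel of a
15-year record. What passing power tests show is that the analysis chain
detects a drift of that signal-to-noise ratio; they do not certify any
particular physical rate of vegetation change, and real data add
seasonality, autocorrelation and spatially correlated weather that the
generator deliberately omits (along with sun-angle geometry, topography,
freezing and fire).

## Statistics

**Mann-Kendall.** S is the signed count of concordant minus discordant
time-ordered pairs; the null variance uses the standard tie correction
`[n(n-1)(2n+5) - sum_t t(t-1)(2t+5)]/18`; Z applies the +/-1 continuity
correction (standard practice at n = 15; a toggle exposes the uncorrected
form since the original choice is undocumented), and p is two-sided
because both trend directions are mapped. Classes: |p| < 0.05 and
0.05 <= p < 0.1 by sign of S, else none; per-pixel class rasters use
integer codes (-2..2, -9 = nodata) with a JSON code sidecar. A series
needs `min_n` valid years (default 10 of 15). The raster path is a
vectorized implementation verified against the scalar one and against an
O(n^2) brute-force oracle; measured type-I error at n = 15 sits near
0.045, within [0.03, 0.07]. No multiple-testing adjustment is applied
across pixels — the maps show raw per-pixel significance, matching
standard practice for this kind of product.

**RMA regression.** slope = sign(r) sd(y)/sd(x), intercept through the
means. Symmetric under axis exchange (slopes reciprocal) and
scale-equivariant; used for platform intercomparison where both axes
carry error.

**Correlation tables.** All pairwise Pearson and Spearman coefficients
over jointly valid pixels (pairwise-complete deletion, because variables
may span different periods), after the precipitation mask; entries with
fewer than 3 joint pixels are NaN. Latitude-like variables should be
passed as absolute values when distance from the equator is the quantity
of interest.

## Grids and files

Pixel-center registration, row-major, origin top-left, axis-aligned
affine transforms only. Downscaling (coarse → fine) is nearest-neighbor;
upscaling (fine → coarse) is the mean of valid contributing pixels with
nodata excluded — constants are preserved in both directions and the
global mean is conserved over fully valid areas. Files are single-band
float32 GeoTIFFs written through tifffile with the standard
georeferencing tags (pixel scale, tiepoint, CRS citation, explicit nodata)
and round-trip losslessly. Ingest refuses "Kelvin" stacks containing
values below 150 K, which indicate Celsius or unscaled integer input;
applying the sensor scale factor is the caller's duty.

The precipitation mask keeps pixels strictly above the threshold
(default 100 mm yr^-1): of the two boundary readings in circulation,
the exclusive one is used, and the operator is configurable.

Annual grouping is by calendar year of the composite start label; cross-
composite day/night pairing is not supported — layers pair by identical
date label and unpaired layers are dropped with a logged count.

## CLI

Four verbs (`simulate`, `annual-rdk`, `trend`, `correlate`) wrap the
library file-in/file-out. Configuration is a flat `key: value` file with
CLI-flag override (CLI > file > defaults), every run logs the package
version, a config hash and per-stage valid-pixel accounting, and exit
codes separate configuration errors (2) from data errors (3). All
thresholds (precipitation 100 mm yr^-1, p levels 0.05/0.1, minimum years
and pairs) are defaults, not constants.

## Problem sizes

Verification experiments use desk-scale problems chosen to make the
properties sharp while keeping runs fast: 100x100 pixels x 46 composites
for the exactness identity, 10,000 white-noise series (n = 15) for
type-I calibration, 1,000 random series against the brute-force oracle,
60x60 scenes for the platform-ordering check, and 40x40 x 15-year scenes
for trend power. Continental-scale headline numbers from real
multi-sensor archives are out of scope by design; the acceptance script
reports what these simulations measure.
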