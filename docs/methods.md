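# Methods

## Scope and model

`coastmhw` analyses long-run change in coastal marine heatwaves (MHWs). The
pipeline has four stages: (1) per-pixel MHW detection in daily SST against a
fixed-baseline day-of-year climatology, (2) accumulation of five MHW metrics
per period (year, or year × season), (3) pixel-averaged aggregation to
biogeographical realms, and (4) a nonparametric trend/change-point suite with
direction classification per realm × season × metric stratum. A synthetic
SST generator supplies ground truth for every stage.

## MHW definition and climatology

Detection follows the standard fixed-baseline percentile definition. For each
day-of-year, all baseline observations within a ±5-day window across baseline
years are pooled; the pooled mean is the seasonally varying climatological
mean and the pooled 90th percentile (linear-interpolation quantile, R type 7)
is the threshold. Both curves are smoothed with a 31-day circular moving
average over day-of-year. A day is flagged when SST strictly exceeds the
threshold (a tie does not flag); maximal runs of at least `min_duration = 5`
flagged days are proto-events, and proto-events separated by at most
`max_gap = 2` non-flagged days are joined into a single event, with the gap
days counting toward the event's duration and intensity metrics. Daily
intensity is SST minus the climatological mean; per event we report duration,
mean, maximum and cumulative (summed) intensity.

Defaults — 90th percentile, 11-day pooling window, 31-day smoother, 5-day
minimum duration, 2-day gap joining, baseline 1983-01-01..2012-12-31 — are
the conventional parameterisation of this definition and are all exposed as
arguments.

**29 February.** Climatologies live on 366 day-of-year slots. Observations
dated 29 Feb are pooled into the 28 Feb bin, pooling windows and the smoother
operate on the 365-position ring with 29 Feb removed, and the 29 Feb
climatology is then set to the mean of the smoothed 28 Feb and 1 Mar values.
Non-leap years simply never index slot 60. The alternative (a 366-ring with
direct calendar distances) moves event boundaries by at most one day; the
test oracle encodes the documented ring explicitly.

**Missing data.** A missing day breaks an exceedance run (it is treated as
non-flagged) and blocks gap-joining across it; a baseline with more than 10%
missing days is rejected. The intended inputs (optimum-interpolation SST
products) are gap-free, so missingness only arises in deliberately degraded
synthetic tests.

## Periods, seasons, and edge effects

Seasons are contiguous three-month blocks, opposite between hemispheres:
north JJA = summer, SON = autumn, DJF = winter, MAM = spring; south mirrored.
December carries the season-year of the following January, so each season is
one unbroken run. A season-year whose block is not fully inside the analysed
span (the first northern winter, the trailing December block) is dropped from
trend series rather than entering as a truncated value. Pixels exactly on the
equator use the northern convention.

Event-day metrics are partitioned by the day's period: days, cumulative
intensity, and the day-weighted mean/max intensity of a period use exactly
the event days falling inside it, so day totals are conserved across period
boundaries; the event *count* is attributed to the period containing the
event's start date, so events are never double-counted. Per-period mean
intensity is a day-weighted mean (not a mean of per-event means); both
choices are internal conventions where the underlying definition is silent.

## Realm aggregation

Count-like metrics (MHW days, number of events, cumulative intensity) scale
with realm size, so realm values are the pixel sum divided by the realm's
total pixel count, making realms directly comparable. Mean and maximum
intensity are averaged over the pixels that had at least one MHW day in the
period: imputing 0 for an event-free pixel would assert "an event exactly at
the climatological mean", which is not a neutral value; an event-free year
therefore yields a missing intensity value (and 0 for the count metrics) in
the yearly series. No area weighting by latitude is applied.

## Trend and change-point suite

For a yearly series x with years t (years, not indices, are the covariate, so
missing years do not distort slopes):

- **Mann–Kendall**: S = Σ_{i<j} sgn(x_j − x_i);
  var(S) = [n(n−1)(2n+5) − Σ_g t_g(t_g−1)(2t_g+5)]/18 over tie groups g;
  z = (S∓1)/√var(S) with the continuity correction, z = 0 for S = 0; p is the
  two-sided normal tail. A fully tied series reports z = 0, p = 1.
- **Theil–Sen**: slope = median of all pairwise slopes; intercept =
  median(x − slope·t) (Conover form, used only to draw trendlines); slopes are
  also reported per decade (×10).
- **Pettitt**: U_t = Σ_{i≤t} Σ_{j>t} sgn(x_i − x_j), K = max|U_t|, earliest
  argmax on ties; p = min(1, 2·exp(−6K²/(n³+n²))). The approximation can
  exceed 1 for weak shifts, hence the clamp. The change year is the year at
  the first index after the split, i.e. the first year of the new regime.
- **Before/after re-fit**: the full suite is re-run on years < change year and
  years ≥ change year; the slope ratio is |after|/|before| (undefined when a
  segment has fewer than 3 usable years or the before-slope is 0).
- **Classification**: increase if p ≤ α and slope > 0, decrease if p ≤ α and
  slope < 0, else no change; α defaults to 0.05, two-sided, with no
  multiple-testing correction across strata (the per-stratum verdicts are
  reported individually; α is a parameter).

Strata need at least 3 non-missing years for the Mann–Kendall/Sen fit and at
least 4 for Pettitt and the before/after re-fit; below those floors the
stratum (respectively the change-point fields) is omitted with a logged
warning for anything under 10 years.

## Synthetic data generator

Each pixel's series is
`mean_level + seasonal_amplitude·sin(2π·doy/365.25 + phase) + trend(t) + ε_t`
on the real Gregorian calendar (leap days included). The trend is piecewise
linear and continuous at 1 January of the change year (slope change, default
0.01 → 0.03 °C/yr at 2002), with an optional level step for exercising
shift-type change points. Residuals ε_t are AR(1) with lag-1 coefficient 0.7
and innovation sd 0.45 °C — daily SST anomalies are strongly persistent, and
downstream stochastic tests must be calibrated against that persistence, not
against white noise. The AR(1) start is drawn from the stationary
distribution. Per-pixel seeds are a CRC32 mix of the master seed and the
pixel id, so grids are extensible without reshuffling existing pixels.
Defaults (mean 15 °C, amplitude 4 °C) represent a mid-latitude coastal pixel;
the 12 standard realm names carry representative hemispheres and latitudes.

Injected events add a trapezoidal anomaly (linear ramps of `ramp_days` inside
a `duration`-day footprint, plateau at `amplitude`). The generator emulates
what matters to the detector and the trend suite — seasonality, persistence,
piecewise trends, discrete warm spells — and deliberately not spatial
covariance between pixels, sea-ice masking, or satellite retrieval error, so
passing tests demonstrate correctness of the computation, not fidelity of
OISST-like spatial error structure.

## Calibration checks and their problem sizes

The test suite and `scripts/acceptance.py` recompute, from scratch:
exhaustive oracle equivalence of S, U_t and the Sen slope on all series of
length ≤ 8 over {0,1,2}; Mann–Kendall type-I error on 10,000 iid Gaussian
series of length 40 (band 0.04–0.06 at α = 0.05); median Sen slope within
0.3 ± 0.05 over 1,000 series with true slope 0.3 under AR(1)(0.3) noise, with
Mann–Kendall power > 95%; and Pettitt localisation of a mean shift of two
*marginal* (stationary) standard deviations at year 21 of 40 within ±2 years
in ≥ 90% of 500 replicates — "2σ" is read on the series' marginal noise scale
because that is the scale on which a shift in central tendency is defined.
The structural check runs the full seasonal pipeline on a 12-realm × 5-pixel,
40-year synthetic grid (exactly 240 strata; day-partition conservation;
realm-average/global consistency on cells covered by all realms). These sizes
keep the whole suite under half a minute while leaving Monte-Carlo error well
inside the stated bands.

## Known limitations

- The Pettitt significance is the classical exponential approximation; it is
  anticonservative for autocorrelated series, as is unadjusted Mann–Kendall
  (no pre-whitening is applied — the suite mirrors the plain tests).
- Detection assumes a fixed baseline; detrended or shifting-baseline
  climatologies, MHW severity categories, and cold-spell detection are out of
  scope.
- Realm aggregation is unweighted by pixel area; at high latitudes pixels are
  smaller, so realm values are pixel averages, not area averages.
- The direction split on synthetic grids reflects the generator's uniform
  warming; it is a functional check of the pipeline, not a reproduction of
  any observed realm-level heterogeneity.
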