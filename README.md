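# coastmhw

Trend and change-point analysis of coastal **marine heatwaves** (MHWs) across
biogeographical realms and seasons.

Marine heatwaves — discrete periods of at least five consecutive days with
sea-surface temperature (SST) above the seasonally varying 90th-percentile
climatological threshold — restructure kelp forests, seagrass meadows and
coral reefs. Whether they are becoming longer, more frequent and more intense
differs between coastal biogeographical realms and between seasons, because
coastal communities share realm-wide temperature tolerances and respond
differently to summer versus winter heat stress. `coastmhw` is a pipeline for
asking exactly that question of multi-decade daily SST: it detects MHWs per
pixel against a fixed-baseline climatology, aggregates five MHW metrics by
year, season and realm, and classifies every realm × season × metric stratum
as increasing, decreasing or unchanged with a nonparametric trend suite.

## Method

**Detection.** For each pixel, the day-of-year climatology pools all baseline
days (default baseline 1983–2012) within ±5 days of each calendar day across
years; the pooled mean and 90th percentile are smoothed with a 31-day
circular moving average. Days with SST strictly above the threshold are
flagged; runs of ≥ 5 flagged days are events, and events separated by ≤ 2
days are joined. Daily intensity is SST − climatological mean. Five metrics
are accumulated per period: MHW days, number of events, mean intensity (°C),
maximum intensity (°C) and cumulative intensity (°C·days).

**Aggregation.** Seasons are the traditional three-month blocks (north:
JJA summer, SON autumn, DJF winter, MAM spring; south: opposite). Realm
values are pixel-averaged: days/events/cumulative intensity are summed and
divided by the realm's pixel count; mean/max intensity are averaged over
event-bearing pixels.

**Inference.** For each yearly series the suite computes the Mann–Kendall
score S = Σ_{i<j} sgn(x_j − x_i) with tie-corrected variance and
continuity-corrected normal deviate; the Theil–Sen slope (median of all
pairwise slopes, reported per decade); and the Pettitt change-point statistic
K = max_t |U_t|, U_t = Σ_{i≤t} Σ_{j>t} sgn(x_i − x_j), with significance
2·exp(−6K²/(n³+n²)) clamped at 1. The trend suite is re-fitted before and
after the change year (the change year opens the "after" regime) and each
stratum is classified: *increase* if p ≤ α and slope > 0, *decrease* if
p ≤ α and slope < 0, else *no change* (α = 0.05).

A synthetic-data module generates daily SST grids with a known seasonal
harmonic, piecewise-linear warming with a change year, AR(1) residuals and
injectable warm events, so every stage can be tested against ground truth.

## Worked example

Run the whole pipeline on a synthetic 12-realm grid (one pixel per realm,
40 years of daily SST, seed 0):

```sh
$ coastmhw run --synth-pixels 1 --seed 0 --out results/demo
240 strata: 26.2% increase, 0.0% decrease, 73.8% no change
```

The run writes `events.csv`, `metric_series.csv`, `strata_results.csv`,
`direction_summary.csv` and a reproducibility manifest into `results/demo`.
Each row of `strata_results.csv` is one realm × season × metric verdict, e.g.

```
Arctic|spring|mhw_days,...,z=3.99,p=0.000065,sen_slope=0.103,...,change_year=2000,...,direction=increase
```

— Arctic spring MHW days rose significantly (about 1.0 day per decade) with a
change point at 2000. With a single noisy pixel per realm only the strongest
strata reach significance; more pixels sharpen the split.

The statistics are also usable directly:

```python
import numpy as np
from coastmhw import mann_kendall, sen_slope, pettitt

years = np.arange(1982, 2022)
days = 25 + 1.2 * (years - 1982) + np.random.default_rng(0).normal(0, 6, 40)
s, var_s, z, p = mann_kendall(days)       # S=640, z=7.45, p=9.7e-14
slope, intercept = sen_slope(days, years) # 1.246 days/yr = 12.46 days/decade
cp = pettitt(days, years)                 # change year 2000, p < 0.001
```

A rising series of yearly MHW days is detected (p ≈ 1e-13), its robust slope
recovered within noise (true 12 days/decade), and a change point located.

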