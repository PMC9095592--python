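"""Season assignment and realm-level aggregation of per-pixel MHW metrics.

Seasons are the traditional three-month blocks, mirrored between hemispheres:
in the north June-August is summer, September-November autumn,
December-February winter and March-May spring; in the south the mapping is
offset by six months. December is labelled with the season-year of the
following January so each season is one contiguous three-month run; the
truncated edge seasons at the start and end of the analysis span are dropped
from trend series.

Realm aggregation is pixel-averaged: the count-like metrics (MHW days, number
of events, cumulative intensity) are summed over pixels and divided by the
realm's pixel count, which makes realms of different sizes directly
comparable; the intensity metrics (mean, max) are averaged over the pixels
that actually had at least one MHW day in the period, since an imputed zero
would mean "event at the climatological mean", not "no event".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "SEASONS",
    "METRICS",
    "COUNT_METRICS",
    "INTENSITY_METRICS",
    "assign_season",
    "season_labels",
    "year_labels",
    "realm_average",
    "build_strata",
]

SEASONS = ("summer", "autumn", "winter", "spring")

#: The five MHW metrics analysed per stratum.
METRICS = (
    "mhw_days",
    "n_events",
    "mean_intensity",
    "max_intensity",
    "cumulative_intensity",
)
COUNT_METRICS = ("mhw_days", "n_events", "cumulative_intensity")
INTENSITY_METRICS = ("mean_intensity", "max_intensity")

_NORTH_SEASON = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}
_MIRROR = {"winter": "summer", "summer": "winter", "spring": "autumn", "autumn": "spring"}


def assign_season(date, hemisphere: str) -> tuple[str, int]:
    """Season and season-year of one date.

    The southern hemisphere uses the opposite seasons; December belongs to the
    season-year of the following January. Pixels exactly on the equator use
    the northern convention.
    """
    if hemisphere not in ("north", "south"):
        raise ValueError(f"hemisphere must be 'north' or 'south', got {hemisphere!r}")
    ts = pd.Timestamp(date)
    season = _NORTH_SEASON[ts.month]
    if hemisphere == "south":
        season = _MIRROR[season]
    season_year = ts.year + 1 if ts.month == 12 else ts.year
    return season, season_year


def season_labels(
    index: pd.DatetimeIndex, hemisphere: str, drop_partial: bool = True
) -> pd.Series:
    """(season_year, season) label for every date, as an object Series.

    With ``drop_partial`` (default), dates belonging to a season that is not
    fully contained in ``index`` — the truncated first winter/summer and the
    trailing December block — are labelled None and excluded downstream.
    """
    if hemisphere not in ("north", "south"):
        raise ValueError(f"hemisphere must be 'north' or 'south', got {hemisphere!r}")
    month = index.month
    season = np.array([_NORTH_SEASON[m] for m in month])
    if hemisphere == "south":
        season = np.array([_MIRROR[s] for s in season])
    season_year = index.year + (month == 12)
    labels = pd.Series(list(zip(season_year, season)), index=index, dtype=object)
    if drop_partial:
        # a season block is complete iff the month before its first month and
        # the month after its last month... simpler: count days per block and
        # compare with the calendar length of that 3-month block
        counts = labels.value_counts()
        for (sy, s), n in counts.items():
            months = [m for m, nm in _NORTH_SEASON.items()
                      if (nm if hemisphere == "north" else _MIRROR[nm]) == s]
            expected = sum(
                pd.Timestamp(year=sy - 1 if m == 12 else sy, month=m, day=1).days_in_month
                for m in months
            )
            if n != expected:
                mask = labels.map(lambda x: x == (sy, s))
                labels[mask] = None
    return labels


def year_labels(index: pd.DatetimeIndex) -> pd.Series:
    """Calendar-year label for every date (annual aggregation)."""
    return pd.Series(index.year, index=index, dtype=object)


def realm_average(period_metrics: pd.DataFrame, realm_table: pd.DataFrame) -> pd.DataFrame:
    """Pixel-averaged realm-level metrics per period.

    ``period_metrics`` is the per-pixel table (pixel_id, period, the five
    metric columns); ``realm_table`` maps pixel_id -> realm. Count-like
    metrics are summed and divided by the realm's total pixel count; intensity
    metrics are averaged over event-bearing pixels only. Returns a tidy frame
    (realm, period, metric, value, n_pixels).
    """
    rt = realm_table[["pixel_id", "realm"]]
    missing = set(period_metrics["pixel_id"]) - set(rt["pixel_id"])
    if missing:
        raise ValueError(f"pixels missing from realm table: {sorted(missing)[:5]}")
    realm_sizes = rt.groupby("realm")["pixel_id"].nunique()
    if (realm_sizes == 0).any():
        raise ValueError("realm with zero pixels")
    df = period_metrics.merge(rt, on="pixel_id")
    rows = []
    for (realm, period), grp in df.groupby(["realm", "period"], observed=True, sort=False):
        n_pixels = int(realm_sizes[realm])
        for metric in COUNT_METRICS:
            rows.append(
                {"realm": realm, "period": period, "metric": metric,
                 "value": grp[metric].sum() / n_pixels, "n_pixels": n_pixels}
            )
        active = grp[grp["mhw_days"] > 0]
        for metric in INTENSITY_METRICS:
            value = active[metric].mean() if len(active) else np.nan
            rows.append(
                {"realm": realm, "period": period, "metric": metric,
                 "value": value, "n_pixels": n_pixels}
            )
    return pd.DataFrame(rows)


def _expand_period(df: pd.DataFrame) -> pd.DataFrame:
    """Split the period key into (year, season) columns."""
    out = df.copy()
    if len(out) and isinstance(out["period"].iloc[0], tuple):
        out["year"] = [p[0] for p in out["period"]]
        out["season"] = [p[1] for p in out["period"]]
    else:
        out["year"] = out["period"].astype(int)
        out["season"] = "annual"
    return out.drop(columns="period")


def build_strata(realm_metrics: pd.DataFrame) -> pd.DataFrame:
    """Assemble one contiguous yearly series per (realm, season, metric).

    Years are made contiguous over each stratum's span: a year with no events
    contributes 0 for the count-like metrics and NaN for the intensity
    metrics. Returns a tidy frame (realm, season, metric, year, value,
    n_pixels) ready for the trend suite.
    """
    df = _expand_period(realm_metrics)
    out = []
    for (realm, season, metric), grp in df.groupby(
        ["realm", "season", "metric"], observed=True, sort=False
    ):
        years = np.arange(grp["year"].min(), grp["year"].max() + 1)
        fill = 0.0 if metric in COUNT_METRICS else np.nan
        series = grp.set_index("year")["value"].reindex(years, fill_value=fill)
        out.append(
            pd.DataFrame(
                {
                    "realm": realm,
                    "season": season,
                    "metric": metric,
                    "year": years,
                    "value": series.to_numpy(),
                    "n_pixels": int(grp["n_pixels"].iloc[0]),
                }
            )
        )
    return pd.concat(out, ignore_index=True)
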