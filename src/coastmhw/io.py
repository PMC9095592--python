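"""Readers and writers for the pipeline's file formats.

Gridded daily SST travels either as CF-style NetCDF (dimensions time/lat/lon,
variable ``sst`` in °C, written with the scipy NetCDF3 backend) or as a
long-format CSV (pixel_id, date, sst_celsius). Pixel-to-realm assignment is a
small CSV (pixel_id, realm, hemisphere, optionally latitude/longitude), and a
JSON "truth" sidecar records the synthetic config and injected events so
ground truth round-trips with the data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .synth import SSTGrid

__all__ = [
    "write_grid_csv",
    "read_grid_csv",
    "write_grid_netcdf",
    "read_grid_netcdf",
    "write_realm_table",
    "read_realm_table",
    "write_truth",
    "read_truth",
    "write_events_csv",
    "write_metric_series_csv",
    "write_strata_csv",
]


def write_grid_csv(grid: SSTGrid, sst_path, realm_path=None, truth_path=None) -> None:
    """Write a grid as long-format CSV (+ optional realm table and truth JSON)."""
    long = grid.sst.stack().rename("sst_celsius").reset_index()
    long.columns = ["date", "pixel_id", "sst_celsius"]
    long = long[["pixel_id", "date", "sst_celsius"]]
    long["date"] = long["date"].dt.strftime("%Y-%m-%d")
    long.to_csv(sst_path, index=False)
    if realm_path is not None:
        write_realm_table(grid.pixels, realm_path)
    if truth_path is not None:
        write_truth(grid.provenance, truth_path)


def read_grid_csv(sst_path, realm_path) -> SSTGrid:
    """Read a long-format SST CSV plus realm table back into an SSTGrid."""
    long = pd.read_csv(sst_path, parse_dates=["date"])
    sst = long.pivot(index="date", columns="pixel_id", values="sst_celsius")
    sst.columns.name = None
    pixels = read_realm_table(realm_path)
    return SSTGrid(pixels=pixels, sst=sst, provenance={})


def write_grid_netcdf(grid: SSTGrid, path) -> None:
    """Write a grid as CF-style NetCDF3 (time/lat/lon dims, variable sst)."""
    lats = np.sort(grid.pixels["latitude"].unique())
    lons = np.sort(grid.pixels["longitude"].unique())
    time = grid.sst.index
    cube = np.full((len(time), len(lats), len(lons)), np.nan, dtype=np.float64)
    lat_pos = {v: i for i, v in enumerate(lats)}
    lon_pos = {v: i for i, v in enumerate(lons)}
    for _, row in grid.pixels.iterrows():
        cube[:, lat_pos[row["latitude"]], lon_pos[row["longitude"]]] = grid.sst[
            row["pixel_id"]
        ].to_numpy()
    ds = xr.Dataset(
        {"sst": (("time", "lat", "lon"), cube, {"units": "degC", "long_name": "sea surface temperature"})},
        coords={"time": time, "lat": lats, "lon": lons},
    )
    ds.attrs["Conventions"] = "CF-1.8"
    ds.to_netcdf(path, engine="scipy")


def read_grid_netcdf(path, realm_table: pd.DataFrame) -> SSTGrid:
    """Read CF-style NetCDF SST; pixels located via the realm table's lat/lon."""
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    columns = {}
    for _, row in realm_table.iterrows():
        cell = ds["sst"].sel(lat=row["latitude"], lon=row["longitude"], method="nearest")
        columns[row["pixel_id"]] = pd.Series(
            cell.to_numpy(), index=pd.DatetimeIndex(ds["time"].to_numpy())
        )
    return SSTGrid(pixels=realm_table, sst=pd.DataFrame(columns), provenance={})


def write_realm_table(pixels: pd.DataFrame, path) -> None:
    pixels.to_csv(path, index=False)


def read_realm_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = {"pixel_id", "realm", "hemisphere"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"realm table missing columns: {sorted(missing)}")
    return table


def write_truth(provenance: dict, path) -> None:
    Path(path).write_text(json.dumps(provenance, indent=2, sort_keys=True))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def write_events_csv(events: list, path) -> None:
    """Write detected MHW events as tidy CSV."""
    rows = [
        {
            "pixel_id": ev.pixel_id,
            "start_date": ev.start_date.isoformat(),
            "end_date": ev.end_date.isoformat(),
            "duration": ev.duration,
            "intensity_mean": ev.intensity_mean,
            "intensity_max": ev.intensity_max,
            "intensity_cumulative": ev.intensity_cumulative,
        }
        for ev in events
    ]
    pd.DataFrame(
        rows,
        columns=[
            "pixel_id", "start_date", "end_date", "duration",
            "intensity_mean", "intensity_max", "intensity_cumulative",
        ],
    ).to_csv(path, index=False, float_format="%.6f")


def write_metric_series_csv(strata: pd.DataFrame, path) -> None:
    """Write the yearly realm-level metric series (tidy) as CSV."""
    strata.to_csv(path, index=False, float_format="%.6f")


def write_strata_csv(results: list, path) -> None:
    """Write per-stratum trend/change-point results as tidy CSV."""
    rows = []
    for r in results:
        rows.append(
            {
                "stratum": r.stratum,
                "realm": r.realm,
                "season": r.season,
                "metric": r.metric,
                "n": r.full.n,
                "S": r.full.s,
                "var_S": r.full.var_s,
                "z": r.full.z,
                "p": r.full.p,
                "sen_slope": r.full.sen_slope,
                "slope_per_decade": r.full.slope_per_decade,
                "intercept": r.full.intercept,
                "change_year": r.change_point.change_year if r.change_point else np.nan,
                "pettitt_p": r.change_point.p if r.change_point else np.nan,
                "before_slope": r.before.sen_slope if r.before else np.nan,
                "after_slope": r.after.sen_slope if r.after else np.nan,
                "slope_ratio": r.slope_ratio,
                "direction": r.direction,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")
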