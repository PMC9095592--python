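"""Synthetic daily SST generator with known ground truth.

Emulates multi-decade gridded daily sea-surface temperature of the kind used
for coastal marine-heatwave studies: a seasonal harmonic, a piecewise-linear
warming trend with an optional change year (continuous slope change by
default, plus an optional level step), AR(1)-autocorrelated daily residuals,
and injectable discrete warm events with trapezoidal shape. Every downstream
stage of the pipeline can therefore be tested against a known truth.

The calendar is the real proleptic Gregorian calendar with leap days, because
the heatwave detector must handle 29 February exactly as it would on real
satellite data.
"""

from __future__ import annotations

import datetime as dt
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SynthConfig",
    "InjectedEvent",
    "SSTSeries",
    "SSTGrid",
    "REALMS",
    "generate_series",
    "inject_events",
    "generate_grid",
]

#: The 12 top-level coastal biogeographical realms (Marine Ecoregions of the
#: World scheme) with a representative hemisphere for synthetic pixels.
REALMS: dict[str, str] = {
    "Arctic": "north",
    "Temperate Northern Atlantic": "north",
    "Temperate Northern Pacific": "north",
    "Tropical Atlantic": "north",
    "Western Indo-Pacific": "north",
    "Central Indo-Pacific": "south",
    "Eastern Indo-Pacific": "south",
    "Tropical Eastern Pacific": "north",
    "Temperate South America": "south",
    "Temperate Southern Africa": "south",
    "Temperate Australasia": "south",
    "Southern Ocean": "south",
}

#: Representative central latitude per realm, consistent with hemisphere.
_REALM_LAT: dict[str, float] = {
    "Arctic": 75.0,
    "Temperate Northern Atlantic": 45.0,
    "Temperate Northern Pacific": 42.0,
    "Tropical Atlantic": 12.0,
    "Western Indo-Pacific": 8.0,
    "Central Indo-Pacific": -5.0,
    "Eastern Indo-Pacific": -10.0,
    "Tropical Eastern Pacific": 5.0,
    "Temperate South America": -40.0,
    "Temperate Southern Africa": -34.0,
    "Temperate Australasia": -38.0,
    "Southern Ocean": -60.0,
}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic daily SST series.

    The deterministic part is
    ``mean_level + seasonal_amplitude * sin(2*pi*doy/365.25 + seasonal_phase)
    + trend(t)`` where the trend is piecewise linear in time (units °C/year),
    continuous at 1 January of ``change_year``, plus an optional
    ``level_step`` added from the change year onward. Residuals are AR(1)
    with innovation standard deviation ``noise_sd`` and lag-1 coefficient
    ``ar_coefficient`` (stationary initialisation).
    """

    start_date: dt.date = dt.date(1982, 1, 1)
    end_date: dt.date = dt.date(2021, 12, 31)
    mean_level: float = 15.0
    seasonal_amplitude: float = 4.0
    seasonal_phase: float = 0.0
    trend_before: float = 0.01
    trend_after: float = 0.03
    change_year: int | None = 2002
    level_step: float = 0.0
    ar_coefficient: float = 0.7
    noise_sd: float = 0.45
    rng_seed: int = 0

    def __post_init__(self):
        start, end = self.start_date, self.end_date
        if isinstance(start, str):
            object.__setattr__(self, "start_date", dt.date.fromisoformat(start))
        if isinstance(end, str):
            object.__setattr__(self, "end_date", dt.date.fromisoformat(end))
        if self.end_date < self.start_date + dt.timedelta(days=730):
            raise ValueError("series must span at least 2 years")
        if not abs(self.ar_coefficient) < 1:
            raise ValueError("|ar_coefficient| must be < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def replace(self, **kwargs) -> "SynthConfig":
        d = asdict(self)
        d.update(kwargs)
        return SynthConfig(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["start_date"] = self.start_date.isoformat()
        d["end_date"] = self.end_date.isoformat()
        return d


@dataclass(frozen=True)
class InjectedEvent:
    """A discrete warm (or cold, if amplitude < 0) anomaly added to one pixel.

    The anomaly footprint spans ``duration`` days from ``onset_date``; within
    it, ``ramp_days`` days ramp linearly up at the start and down at the end,
    with the plateau at ``amplitude`` °C in between.
    """

    pixel_id: str
    onset_date: dt.date
    duration: int
    amplitude: float
    ramp_days: int = 0

    def __post_init__(self):
        if isinstance(self.onset_date, str):
            object.__setattr__(self, "onset_date", dt.date.fromisoformat(self.onset_date))
        if self.duration < 1:
            raise ValueError("duration must be >= 1")
        if self.ramp_days < 0:
            raise ValueError("ramp_days must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["onset_date"] = self.onset_date.isoformat()
        return d


@dataclass
class SSTSeries:
    """One pixel's dated daily sea-surface temperatures (°C)."""

    pixel_id: str
    data: pd.Series  # DatetimeIndex -> sst °C, strictly increasing dates

    def __post_init__(self):
        if not self.data.index.is_monotonic_increasing or self.data.index.has_duplicates:
            raise ValueError("dates must be strictly increasing")


@dataclass
class SSTGrid:
    """A set of pixels with realm labels plus per-pixel daily series.

    ``pixels`` has columns pixel_id, latitude, longitude, realm, hemisphere;
    ``sst`` is wide (DatetimeIndex rows, one column per pixel_id);
    ``provenance`` records the generating config and injected-event truth.
    """

    pixels: pd.DataFrame
    sst: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def series(self, pixel_id: str) -> SSTSeries:
        return SSTSeries(pixel_id, self.sst[pixel_id])


def _seasonal_and_trend(config: SynthConfig, index: pd.DatetimeIndex) -> np.ndarray:
    doy = index.dayofyear.to_numpy(dtype=float)
    seasonal = config.seasonal_amplitude * np.sin(
        2 * np.pi * doy / 365.25 + config.seasonal_phase
    )
    t_years = (index - index[0]).days.to_numpy(dtype=float) / 365.25
    if config.change_year is None:
        trend = config.trend_before * t_years
    else:
        joint = pd.Timestamp(dt.date(config.change_year, 1, 1))
        if not (index[0] < joint <= index[-1]):
            raise ValueError("change_year must fall inside the series span")
        t_joint = (joint - index[0]).days / 365.25
        trend = np.where(
            t_years < t_joint,
            config.trend_before * t_years,
            config.trend_before * t_joint + config.trend_after * (t_years - t_joint),
        )
        trend = trend + np.where(t_years >= t_joint, config.level_step, 0.0)
    return config.mean_level + seasonal + trend


def _ar1_noise(n: int, ar: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd, size=n)
    x = np.empty(n)
    # stationary start so early years are not systematically calmer
    x[0] = rng.normal(0.0, sd / np.sqrt(1 - ar * ar)) if ar != 0 else eps[0]
    for t in range(1, n):
        x[t] = ar * x[t - 1] + eps[t]
    return x


def pixel_seed(master_seed: int, pixel_id: str) -> int:
    """Stable per-pixel seed: CRC32 mix of master seed and pixel id.

    Independent of the number or order of other pixels, so grids are
    extensible without reshuffling existing pixels.
    """
    return zlib.crc32(f"{master_seed}:{pixel_id}".encode()) & 0x7FFFFFFF


def generate_series(config: SynthConfig, pixel_id: str = "px0") -> SSTSeries:
    """Generate one synthetic daily SST series. Deterministic given config."""
    index = pd.date_range(config.start_date, config.end_date, freq="D")
    rng = np.random.default_rng(config.rng_seed)
    values = _seasonal_and_trend(config, index) + _ar1_noise(
        len(index), config.ar_coefficient, config.noise_sd, rng
    )
    return SSTSeries(pixel_id, pd.Series(values, index=index, name="sst_celsius"))


def _event_offsets(event: InjectedEvent) -> np.ndarray:
    i = np.arange(event.duration, dtype=float)
    denom = event.ramp_days + 1.0
    factor = np.minimum(1.0, np.minimum((i + 1) / denom, (event.duration - i) / denom))
    return event.amplitude * factor


def inject_events(series: SSTSeries, events: list[InjectedEvent]) -> SSTSeries:
    """Return a copy of the series with trapezoidal anomalies added.

    The input series is left unmodified. Each event must lie fully within the
    series span.
    """
    data = series.data.copy()
    for ev in events:
        start = pd.Timestamp(ev.onset_date)
        end = start + pd.Timedelta(days=ev.duration - 1)
        if start < data.index[0] or end > data.index[-1]:
            raise ValueError(f"event {ev} outside series span")
        sl = data.index.slice_indexer(start, end)
        offsets = _event_offsets(ev)
        if sl.stop - sl.start != ev.duration:
            # missing days inside the footprint: add only where days exist
            present = data.index[sl]
            pos = (present - start).days.to_numpy()
            data.iloc[sl] += offsets[pos]
        else:
            data.iloc[sl] += offsets
    return SSTSeries(series.pixel_id, data)


def generate_grid(
    n_pixels_per_realm: dict[str, int],
    config: SynthConfig,
    per_realm_overrides: dict[str, dict] | None = None,
    events: list[InjectedEvent] | None = None,
    hemispheres: dict[str, str] | None = None,
) -> SSTGrid:
    """Generate a multi-pixel grid with independent noise per pixel.

    Each pixel's RNG seed derives from the master seed and the pixel id, so
    adding realms or pixels never changes existing pixels.
    ``per_realm_overrides`` maps realm -> SynthConfig field overrides (e.g. a
    steeper post-change trend for one realm). Realm names outside the 12
    standard realms are allowed; supply their hemisphere via ``hemispheres``.
    """
    overrides = per_realm_overrides or {}
    events = events or []
    rows = []
    columns = {}
    for r_idx, (realm, count) in enumerate(n_pixels_per_realm.items()):
        if count < 1:
            raise ValueError(f"realm {realm!r} needs >= 1 pixel")
        hemi = (hemispheres or {}).get(realm) or REALMS.get(realm)
        if hemi is None:
            raise ValueError(f"unknown realm {realm!r}: supply its hemisphere")
        lat = _REALM_LAT.get(realm, 45.0 if hemi == "north" else -45.0)
        realm_cfg = config.replace(**overrides.get(realm, {}))
        for p in range(count):
            pixel_id = f"{realm.replace(' ', '_')}_{p}"
            cfg = realm_cfg.replace(rng_seed=pixel_seed(config.rng_seed, pixel_id))
            series = generate_series(cfg, pixel_id)
            rows.append(
                {
                    "pixel_id": pixel_id,
                    "latitude": lat,
                    "longitude": -180.0 + 0.25 * (r_idx * 64 + p),
                    "realm": realm,
                    "hemisphere": hemi,
                }
            )
            columns[pixel_id] = series.data
    sst = pd.DataFrame(columns)
    by_pixel: dict[str, list[InjectedEvent]] = {}
    for ev in events:
        by_pixel.setdefault(ev.pixel_id, []).append(ev)
    for pid, evs in by_pixel.items():
        if pid not in sst.columns:
            raise ValueError(f"injected event targets unknown pixel {pid!r}")
        sst[pid] = inject_events(SSTSeries(pid, sst[pid]), evs).data
    provenance = {
        "config": config.to_dict(),
        "per_realm_overrides": overrides,
        "injected_events": [ev.to_dict() for ev in events],
    }
    return SSTGrid(pixels=pd.DataFrame(rows), sst=sst, provenance=provenance)
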