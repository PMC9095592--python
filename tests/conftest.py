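import datetime as dt

import numpy as np
import pandas as pd
import pytest

from coastmhw import SSTSeries, SynthConfig
from coastmhw.detect import Climatology


@pytest.fixture
def quiet_config():
    """Noise-free, trend-free harmonic over a decade."""
    return SynthConfig(
        start_date=dt.date(1990, 1, 1),
        end_date=dt.date(1999, 12, 31),
        mean_level=12.0,
        seasonal_amplitude=3.0,
        trend_before=0.0,
        trend_after=0.0,
        change_year=None,
        ar_coefficient=0.0,
        noise_sd=0.0,
        rng_seed=7,
    )


@pytest.fixture
def constant_climatology():
    """Flat climatology: mean 10 degC, threshold 11 degC on every day-of-year."""
    return Climatology(
        clim_mean=np.full(366, 10.0),
        clim_threshold=np.full(366, 11.0),
        baseline_start=dt.date(1983, 1, 1),
        baseline_end=dt.date(2012, 12, 31),
    )


def make_series(values, start="2000-01-01", pixel_id="px0"):
    index = pd.date_range(start, periods=len(values), freq="D")
    return SSTSeries(pixel_id, pd.Series(np.asarray(values, dtype=float), index=index))


@pytest.fixture
def series_factory():
    return make_series
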