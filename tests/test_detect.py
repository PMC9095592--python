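"""Tests for climatology construction and MHW event detection.

The independent oracle for detection is an explicit flag/run/merge scan; the
climatology oracle is explicit pooling + sorting without any vectorised
shortcuts.
"""

import datetime as dt
import itertools

import numpy as np
import pandas as pd
import pytest

from coastmhw import SynthConfig, compute_climatology, detect_events, generate_series
from coastmhw.detect import Climatology, doy_slot, summarize_periods
from coastmhw.synth import SSTSeries


# ---------------------------------------------------------------- oracles


def brute_force_events(flags, min_duration=5, max_gap=2):
    """Enumerate event index spans [(start, end)] from a boolean flag list."""
    runs, start = [], None
    for i, f in enumerate(list(flags) + [False]):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i - 1))
            start = None
    proto = [(s, e) for s, e in runs if e - s + 1 >= min_duration]
    merged = []
    for s, e in proto:
        if merged and s - merged[-1][1] - 1 <= max_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def _nonleap_ordinal(month, day):
    """Position on the 365-day ring; 29 Feb shares 28 Feb's position."""
    if (month, day) == (2, 29):
        month, day = 2, 28
    return dt.date(2001, month, day).timetuple().tm_yday


def brute_force_climatology(dates, values, target_md, half_width=5):
    """Pool baseline values within +/-half_width positions on the 365-day ring."""
    ref = _nonleap_ordinal(*target_md)
    pooled = []
    for d, v in zip(dates, values):
        delta = abs(_nonleap_ordinal(d.month, d.day) - ref)
        delta = min(delta, 365 - delta)
        if delta <= half_width:
            pooled.append(v)
    return pooled


def flags_to_series(flags, start="2000-01-01"):
    """SST 12 where flagged else 10, against a flat climatology mean 10 / thresh 11."""
    values = [12.0 if f else 10.0 for f in flags]
    index = pd.date_range(start, periods=len(values), freq="D")
    return SSTSeries("px0", pd.Series(values, index=index, dtype=float))


# ---------------------------------------------------------------- climatology


class TestClimatology:
    def test_constant_series_gives_flat_climatology(self, series_factory):
        series = series_factory([10.0] * (365 * 3 + 1), start="1990-01-01")
        clim = compute_climatology(series, dt.date(1990, 1, 1), dt.date(1992, 12, 31))
        assert np.allclose(clim.clim_mean, 10.0)
        assert np.allclose(clim.clim_threshold, 10.0)

    def test_harmonic_mean_tracked_with_smoother_attenuation(self):
        cfg = SynthConfig(
            start_date=dt.date(1983, 1, 1),
            end_date=dt.date(2012, 12, 31),
            mean_level=12.0,
            seasonal_amplitude=3.0,
            trend_before=0.0,
            trend_after=0.0,
            change_year=None,
            ar_coefficient=0.0,
            noise_sd=0.0,
        )
        series = generate_series(cfg)
        clim = compute_climatology(series, dt.date(1983, 1, 1), dt.date(2012, 12, 31))
        # 41-day effective window (11-day pooling then 31-day smoothing) on an
        # annual harmonic attenuates the amplitude by at most a few percent
        # and cannot amplify it
        amp = (clim.clim_mean.max() - clim.clim_mean.min()) / 2
        assert 0.9 * 3.0 < amp <= 3.0 + 1e-9
        # threshold ~ mean when the only spread is the within-window harmonic drift
        spread = clim.clim_threshold - clim.clim_mean
        assert spread.max() < 0.25

    def test_threshold_equals_pooled_percentile_oracle(self, series_factory):
        rng = np.random.default_rng(11)
        n = 365 * 4 + 1
        values = rng.normal(15.0, 2.0, size=n)
        series = series_factory(values, start="1990-01-01")
        clim = compute_climatology(
            series,
            dt.date(1990, 1, 1),
            dt.date(1993, 12, 31),
            smooth_width=1,  # disable smoothing to expose raw pooled values
        )
        dates = [d.date() for d in series.data.index]
        for month, day in [(1, 15), (7, 1), (12, 31), (3, 1)]:
            pooled = brute_force_climatology(dates, values, (month, day))
            slot = doy_slot(pd.DatetimeIndex([f"2000-{month:02d}-{day:02d}"]))[0]
            assert clim.clim_threshold[slot - 1] == pytest.approx(
                np.percentile(pooled, 90), abs=1e-9
            )
            assert clim.clim_mean[slot - 1] == pytest.approx(np.mean(pooled), abs=1e-9)

    def test_feb29_is_average_of_neighbours(self, series_factory):
        rng = np.random.default_rng(3)
        values = rng.normal(10, 1, size=365 * 4 + 1)
        series = series_factory(values, start="1990-01-01")
        clim = compute_climatology(series, dt.date(1990, 1, 1), dt.date(1993, 12, 31))
        feb28 = doy_slot(pd.DatetimeIndex(["2000-02-28"]))[0] - 1
        feb29 = doy_slot(pd.DatetimeIndex(["2000-02-29"]))[0] - 1
        mar1 = doy_slot(pd.DatetimeIndex(["2000-03-01"]))[0] - 1
        assert clim.clim_mean[feb29] == pytest.approx(
            0.5 * (clim.clim_mean[feb28] + clim.clim_mean[mar1])
        )

    def test_short_baseline_rejected(self, series_factory):
        series = series_factory([10.0] * 400, start="1990-01-01")
        with pytest.raises(ValueError):
            compute_climatology(series, dt.date(1990, 1, 1), dt.date(1991, 1, 1))

    def test_gappy_baseline_rejected(self, series_factory):
        values = pd.Series(
            10.0, index=pd.date_range("1990-01-01", "1992-12-31", freq="D")
        )
        gappy = values.drop(values.index[100:260])  # ~15% missing
        with pytest.raises(ValueError, match="missing"):
            compute_climatology(
                SSTSeries("px0", gappy), dt.date(1990, 1, 1), dt.date(1992, 12, 31)
            )

    def test_pathological_threshold_below_mean_raises(self):
        with pytest.raises(ValueError, match="pathological"):
            Climatology(
                clim_mean=np.full(366, 10.0),
                clim_threshold=np.full(366, 9.0),
                baseline_start=dt.date(1990, 1, 1),
                baseline_end=dt.date(1992, 12, 31),
            )


# ---------------------------------------------------------------- detection


class TestDetectEvents:
    def test_series_below_threshold_yields_no_events(self, constant_climatology):
        series = flags_to_series([False] * 60)
        assert detect_events(series, constant_climatology) == []

    def test_ten_day_block_metrics(self, constant_climatology):
        flags = [False] * 20 + [True] * 10 + [False] * 30
        events = detect_events(flags_to_series(flags), constant_climatology)
        assert len(events) == 1
        ev = events[0]
        assert ev.duration == 10
        assert ev.intensity_mean == pytest.approx(2.0)
        assert ev.intensity_max == pytest.approx(2.0)
        assert ev.intensity_cumulative == pytest.approx(20.0)
        assert ev.start_date == dt.date(2000, 1, 21)
        assert ev.end_date == dt.date(2000, 1, 30)

    def test_four_day_block_is_not_an_event(self, constant_climatology):
        flags = [False] * 10 + [True] * 4 + [False] * 10
        assert detect_events(flags_to_series(flags), constant_climatology) == []

    def test_two_runs_bridged_by_two_day_gap_merge(self, constant_climatology):
        flags = [False] * 5 + [True] * 5 + [False] * 2 + [True] * 5 + [False] * 5
        events = detect_events(flags_to_series(flags), constant_climatology)
        assert len(events) == 1
        assert events[0].duration == 12
        # gap days sit at the climatological mean: anomaly 0 dilutes the mean
        assert events[0].intensity_cumulative == pytest.approx(20.0)
        assert events[0].intensity_mean == pytest.approx(20.0 / 12)

    def test_three_day_gap_keeps_events_separate(self, constant_climatology):
        flags = [False] * 5 + [True] * 5 + [False] * 3 + [True] * 5 + [False] * 5
        events = detect_events(flags_to_series(flags), constant_climatology)
        assert [ev.duration for ev in events] == [5, 5]

    def test_tie_at_threshold_does_not_flag(self, constant_climatology):
        series_values = [11.0] * 30  # exactly at the threshold
        index = pd.date_range("2000-01-01", periods=30, freq="D")
        series = SSTSeries("px0", pd.Series(series_values, index=index))
        assert detect_events(series, constant_climatology) == []

    def test_missing_day_breaks_run(self, constant_climatology):
        index = pd.date_range("2000-01-01", periods=20, freq="D").delete(10)
        values = pd.Series(12.0, index=index)
        events = detect_events(SSTSeries("px0", values), constant_climatology)
        assert [ev.duration for ev in events] == [10, 9]

    def test_constant_offset_invariance(self, constant_climatology):
        flags = [False] * 8 + [True] * 7 + [False] * 8
        series = flags_to_series(flags)
        shifted = SSTSeries("px0", series.data + 5.0)
        clim_shifted = Climatology(
            clim_mean=constant_climatology.clim_mean + 5.0,
            clim_threshold=constant_climatology.clim_threshold + 5.0,
            baseline_start=constant_climatology.baseline_start,
            baseline_end=constant_climatology.baseline_end,
        )
        base = detect_events(series, constant_climatology)
        moved = detect_events(shifted, clim_shifted)
        assert [(e.start_date, e.duration, e.intensity_cumulative) for e in base] == [
            (e.start_date, e.duration, e.intensity_cumulative) for e in moved
        ]

    def test_matches_run_merge_oracle_on_all_short_flag_patterns(
        self, constant_climatology
    ):
        # exhaustive over all flag patterns of length 12 (4096 cases) plus a
        # seeded sample of longer ones
        for n, patterns in [
            (12, itertools.product([False, True], repeat=12)),
        ]:
            for flags in patterns:
                events = detect_events(flags_to_series(flags), constant_climatology)
                expected = brute_force_events(flags)
                got = [
                    (
                        (pd.Timestamp(e.start_date) - pd.Timestamp("2000-01-01")).days,
                        (pd.Timestamp(e.end_date) - pd.Timestamp("2000-01-01")).days,
                    )
                    for e in events
                ]
                assert got == expected, f"flags={flags}"
        rng = np.random.default_rng(5)
        for _ in range(200):
            flags = rng.random(40) < 0.5
            events = detect_events(flags_to_series(flags), constant_climatology)
            got = [
                (
                    (pd.Timestamp(e.start_date) - pd.Timestamp("2000-01-01")).days,
                    (pd.Timestamp(e.end_date) - pd.Timestamp("2000-01-01")).days,
                )
                for e in events
            ]
            assert got == brute_force_events(flags)


# ---------------------------------------------------------------- period summary


class TestSummarizePeriods:
    def _labels(self, index, boundary):
        """Two periods split at a boundary date."""
        return pd.Series(
            np.where(index < pd.Timestamp(boundary), "P1", "P2"), index=index, dtype=object
        )

    def test_period_without_events_reports_zeros(self, constant_climatology):
        series = flags_to_series([False] * 30)
        labels = self._labels(series.data.index, "2000-01-16")
        out = summarize_periods(series, constant_climatology, [], labels)
        assert (out["mhw_days"] == 0).all()
        assert (out["n_events"] == 0).all()
        assert (out["cumulative_intensity"] == 0).all()
        assert out["mean_intensity"].isna().all()

    def test_event_fully_inside_one_period(self, constant_climatology):
        flags = [False] * 5 + [True] * 10 + [False] * 15
        series = flags_to_series(flags)
        events = detect_events(series, constant_climatology)
        labels = self._labels(series.data.index, "2000-01-21")
        out = summarize_periods(series, constant_climatology, events, labels).set_index("period")
        assert out.loc["P1", "mhw_days"] == 10
        assert out.loc["P1", "n_events"] == 1
        assert out.loc["P1", "mean_intensity"] == pytest.approx(2.0)
        assert out.loc["P1", "cumulative_intensity"] == pytest.approx(20.0)
        assert out.loc["P2", "mhw_days"] == 0

    def test_event_straddling_boundary_partitions_days(self, constant_climatology):
        # 10-day event: 6 days in P1, 4 in P2; the event count goes to P1 only
        flags = [False] * 5 + [True] * 10 + [False] * 15
        series = flags_to_series(flags)
        events = detect_events(series, constant_climatology)
        labels = self._labels(series.data.index, "2000-01-12")  # split after day 11
        out = summarize_periods(series, constant_climatology, events, labels).set_index("period")
        assert out.loc["P1", "mhw_days"] == 6
        assert out.loc["P1", "cumulative_intensity"] == pytest.approx(12.0)
        assert out.loc["P1", "n_events"] == 1
        assert out.loc["P2", "mhw_days"] == 4
        assert out.loc["P2", "cumulative_intensity"] == pytest.approx(8.0)
        assert out.loc["P2", "n_events"] == 0

    def test_day_partition_conservation(self, constant_climatology):
        rng = np.random.default_rng(9)
        flags = rng.random(120) < 0.4
        series = flags_to_series(flags)
        events = detect_events(series, constant_climatology)
        total_days = sum(ev.duration for ev in events)
        total_cum = sum(ev.intensity_cumulative for ev in events)
        labels = pd.Series(
            np.repeat(["A", "B", "C", "D"], 30), index=series.data.index, dtype=object
        )
        out = summarize_periods(series, constant_climatology, events, labels)
        assert out["mhw_days"].sum() == total_days
        assert out["cumulative_intensity"].sum() == pytest.approx(total_cum)
        assert out["n_events"].sum() == len(events)
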