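"""Event definitions, thresholds, run detection and day/night classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import thermex as tx
from thermex import events as ev

from conftest import brute_force_classify, brute_force_flags


class TestEnumerateDefinitions:
    def test_heat_grid(self):
        defs = tx.enumerate_definitions(ev.HEAT_WAVE)
        assert len(defs) == 18
        assert {d.percentile for d in defs} == set(ev.HEAT_PERCENTILES)
        assert {d.min_duration for d in defs} == {2, 3}

    def test_cold_grid(self):
        defs = tx.enumerate_definitions(ev.COLD_SPELL)
        assert len(defs) == 18
        assert {d.percentile for d in defs} == set(ev.COLD_PERCENTILES)

    def test_grids_disjoint_and_deterministic(self):
        heat = tx.enumerate_definitions(ev.HEAT_WAVE)
        cold = tx.enumerate_definitions(ev.COLD_SPELL)
        assert not {(d.kind, d.percentile) for d in heat} & {
            (d.kind, d.percentile) for d in cold
        }
        assert heat == tx.enumerate_definitions(ev.HEAT_WAVE)

    def test_invalid_kind_rejected(self):
        with pytest.raises(ValueError):
            tx.enumerate_definitions("typhoon")
        with pytest.raises(ValueError):
            ev.EventDefinition(ev.HEAT_WAVE, 50.0, 2)
        with pytest.raises(ValueError):
            ev.EventDefinition(ev.HEAT_WAVE, 90.0, 4)


class TestThreshold:
    def test_constant_series(self):
        for p in ev.HEAT_PERCENTILES:
            assert tx.compute_threshold(np.full(40, 21.5), p) == 21.5

    def test_linear_interpolation_rule(self):
        assert tx.compute_threshold(np.array([10.0, 20, 30, 40]), 25) == 17.5
        assert tx.compute_threshold(np.arange(1.0, 102.0), 90) == 91.0

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            tx.compute_threshold(np.full(50, np.nan), 90)

    def test_missing_values_ignored(self):
        vals = np.arange(1.0, 102.0)
        with_nan = np.concatenate([vals, [np.nan] * 10])
        assert tx.compute_threshold(with_nan, 90) == 91.0


class TestFlagEventDays:
    @pytest.mark.parametrize(
        "series, thr, direction, dur, expected",
        [
            ([30, 31, 32, 29, 33], 30, "ge", 3, [1, 1, 1, 0, 0]),
            ([30, 29, 30], 30, "ge", 2, [0, 0, 0]),
            ([1, 2, 3], 10, "ge", 2, [0, 0, 0]),
            ([5, 4, 4, 9, 3, 3, 3], 4, "le", 2, [0, 1, 1, 0, 1, 1, 1]),
        ],
    )
    def test_run_examples(self, series, thr, direction, dur, expected):
        got = tx.flag_event_days(np.array(series, float), thr, direction, dur)
        assert got.tolist() == [bool(e) for e in expected]

    def test_missing_days_break_runs(self):
        series = np.array([31.0, np.nan, 31.0, 31.0, 31.0])
        got = tx.flag_event_days(series, 30, "ge", 3)
        assert got.tolist() == [False, False, True, True, True]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.normal(25, 5, 300)
            x[rng.random(300) < 0.02] = np.nan
            thr = float(np.nanquantile(x, 0.8))
            for dur in (2, 3):
                got = tx.flag_event_days(x, thr, "ge", dur)
                assert np.array_equal(got, brute_force_flags(x, thr, "ge", dur))

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=-10, max_value=10), min_size=1, max_size=60),
        st.sampled_from([2, 3]),
    )
    def test_flags_property(self, vals, dur):
        x = np.array(vals)
        flags = tx.flag_event_days(x, 0.0, "ge", dur)
        # flagged days qualify, and sit in runs of at least `dur`
        assert not np.any(flags & (x < 0))
        assert np.array_equal(flags, brute_force_flags(x, 0.0, "ge", dur))


class TestClassify:
    def test_truth_table(self):
        day = np.array([True, True, False, False])
        night = np.array([True, False, True, False])
        assert tx.classify_events(day, night).tolist() == [
            "compound", "daytime_only", "nighttime_only", "none",
        ]

    def test_misaligned_inputs_error(self):
        with pytest.raises(ValueError):
            tx.classify_events(np.zeros(3, bool), np.zeros(4, bool))

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=50))
    def test_exactly_one_label_per_day(self, pairs):
        day = np.array([p[0] for p in pairs])
        night = np.array([p[1] for p in pairs])
        got = tx.classify_events(day, night)
        assert np.array_equal(got, brute_force_classify(day, night))
        assert set(got) <= {"none", *ev.EVENT_TYPES}


class TestMonotonicity:
    def test_threshold_monotonicity_heat(self, random_weather):
        w = random_weather
        mask = ev.season_mask(w["date"], ev.HEAT_WAVE)
        x = w["tmax"].to_numpy()[mask]
        for dur in (2, 3):
            prev = None
            for p in ev.HEAT_PERCENTILES:
                thr = tx.compute_threshold(x, p)
                flags = tx.flag_event_days(x, thr, "ge", dur)
                if prev is not None:
                    assert np.all(flags <= prev)  # higher percentile: subset
                prev = flags

    def test_threshold_monotonicity_cold(self, random_weather):
        w = random_weather
        mask = ev.season_mask(w["date"], ev.COLD_SPELL)
        x = w["tmin"].to_numpy()[mask]
        for dur in (2, 3):
            prev = None
            for p in ev.COLD_PERCENTILES:  # descending severity order
                thr = tx.compute_threshold(x, p)
                flags = tx.flag_event_days(x, thr, "le", dur)
                if prev is not None:
                    assert np.all(flags <= prev)
                prev = flags

    def test_duration_monotonicity(self, random_weather):
        w = random_weather
        x = w["tmax"].to_numpy()
        thr = tx.compute_threshold(x, 80.0)
        f2 = tx.flag_event_days(x, thr, "ge", 2)
        f3 = tx.flag_event_days(x, thr, "ge", 3)
        assert np.all(f3 <= f2)


class TestCalendar:
    def test_season_restriction(self, random_weather):
        w = random_weather
        cal = tx.build_event_calendar(
            w["date"], w["tmax"].to_numpy(), w["tmin"].to_numpy(),
            ev.EventDefinition(ev.HEAT_WAVE, 75.0, 2),
        )
        months = pd.DatetimeIndex(cal["date"]).month
        off = ~np.isin(months, ev.HOT_SEASON_MONTHS)
        assert (cal.loc[off, "event_type"] == "none").all()
        assert not cal.loc[off, "day_flag"].any()

    def test_cold_runs_cross_new_year(self):
        dates = pd.date_range("2007-12-28", "2008-01-05", freq="D")
        tmin = np.array([0, 0, -9, -9, -9, -9, 0, 0, 0], dtype=float)
        tmax = tmin + 8
        flags = np.zeros(len(dates), bool)
        for block in ev.season_blocks(dates, ev.COLD_SPELL):
            assert block.size == len(dates)  # one block across 31 Dec
            flags[block] = tx.flag_event_days(tmin[block], -5, "le", 3)
        assert flags.tolist() == [0, 0, 1, 1, 1, 1, 0, 0, 0]

    def test_date_gap_breaks_blocks(self):
        dates = pd.DatetimeIndex(
            list(pd.date_range("2007-06-01", "2007-06-03"))
            + list(pd.date_range("2007-06-05", "2007-06-07"))
        )
        blocks = ev.season_blocks(dates, ev.HEAT_WAVE)
        assert [b.size for b in blocks] == [3, 3]

    def test_compound_iff_both_flags(self, random_weather):
        w = random_weather
        cal = tx.build_event_calendar(
            w["date"], w["tmax"].to_numpy(), w["tmin"].to_numpy(),
            ev.EventDefinition(ev.HEAT_WAVE, 80.0, 2),
        )
        comp = cal["event_type"] == "compound"
        assert (comp == (cal["day_flag"] & cal["night_flag"])).all()


class TestHumiditySplit:
    def _calendar(self, random_weather):
        w = random_weather
        return w, tx.build_event_calendar(
            w["date"], w["tmax"].to_numpy(), w["tmin"].to_numpy(),
            ev.EventDefinition(ev.HEAT_WAVE, 75.0, 2),
        )

    def test_tie_goes_high(self, random_weather):
        w, cal = self._calendar(random_weather)
        rh = np.full(len(cal), 60.0)
        out = tx.split_by_humidity(cal, rh, cutoff=60.0)
        on_event = out["event_type"] != "none"
        assert (out.loc[on_event, "humidity_stratum"] == ev.HIGH).all()

    def test_all_below_cutoff_low(self, random_weather):
        w, cal = self._calendar(random_weather)
        out = tx.split_by_humidity(cal, np.full(len(cal), 10.0), cutoff=60.0)
        on_event = out["event_type"] != "none"
        assert (out.loc[on_event, "humidity_stratum"] == ev.LOW).all()
        assert (out.loc[~on_event, "humidity_stratum"] == ev.NOT_APPLICABLE).all()

    def test_partition_conserves_event_days(self, random_weather):
        w, cal = self._calendar(random_weather)
        rh = w["rh"].to_numpy().copy()
        rh[5] = np.nan
        out = tx.split_by_humidity(cal, rh, cutoff=65.0)
        n_event_finite = int(((out["event_type"] != "none") & np.isfinite(rh)).sum())
        n_low = int((out["humidity_stratum"] == ev.LOW).sum())
        n_high = int((out["humidity_stratum"] == ev.HIGH).sum())
        assert n_low + n_high == n_event_finite


class TestNationalMedian:
    def test_constant_single_community(self):
        dates = pd.date_range("2007-01-01", "2007-12-31")
        panel = pd.DataFrame({"date": dates, "rh": np.full(len(dates), 65.8)})
        assert tx.national_rh_median([panel]) == 65.8

    def test_pooled_median_two_communities(self):
        dates = pd.date_range("2007-06-01", "2007-06-30")
        a = pd.DataFrame({"date": dates, "rh": np.full(len(dates), 40.0)})
        b = pd.DataFrame({"date": dates, "rh": np.full(len(dates), 80.0)})
        assert tx.national_rh_median([a, b]) == 60.0

    def test_duplication_invariance(self, random_weather):
        w = random_weather
        once = tx.national_rh_median([w])
        assert tx.national_rh_median([w, w, w]) == once


class TestAnnualEventDays:
    def test_empty_calendar(self):
        cal = pd.DataFrame({"date": pd.DatetimeIndex([]), "event_type": []})
        assert tx.annual_event_days(cal) == {t: 0.0 for t in ev.EVENT_TYPES}

    def test_seven_year_average(self):
        dates = pd.date_range("2007-01-01", "2013-12-31")
        types = np.full(len(dates), "none", dtype=object)
        types[:28] = "compound"
        cal = pd.DataFrame({"date": dates, "event_type": types})
        assert tx.annual_event_days(cal)["compound"] == 4.0

    def test_counts_partition_flagged_days(self, random_weather):
        w = random_weather
        cal = tx.build_event_calendar(
            w["date"], w["tmax"].to_numpy(), w["tmin"].to_numpy(),
            ev.EventDefinition(ev.HEAT_WAVE, 77.5, 2),
        )
        per_type = tx.annual_event_days(cal)
        n_years = pd.DatetimeIndex(cal["date"]).year.nunique()
        total_flagged = int((cal["event_type"] != "none").sum())
        assert sum(per_type.values()) * n_years == pytest.approx(total_flagged)
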