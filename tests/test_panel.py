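"""Panel assembly, exclusion rule, decomposition and imputation."""

from datetime import date, datetime, time, timedelta
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd
import pytest

from somnus import panel as panel_mod
from somnus.inbed import InBedInterval
from somnus.io_ingest import DailyUsageTotal, SleepStage, SleepStageRecord, UsageHour
from somnus.panel import (
    aggregate_sleep,
    assemble_panel,
    compute_suib,
    compute_tsu,
    decompose,
    filter_missing,
    impute,
)

TZ = ZoneInfo("Europe/Brussels")


def sleep_rec(stage, start, end):
    return SleepStageRecord("p", SleepStage(stage), start, end)


class TestAggregateSleep:
    def test_stage_sums_and_total(self):
        """REM 1.55 h + core 4.98 h + deep 0.73 h gives 7.26 h total."""
        t0 = datetime(2024, 3, 4, 23, 0, tzinfo=TZ)
        records = []
        cur = t0
        for stage, hours in [("core", 4.98), ("deep", 0.73), ("rem", 1.55)]:
            end = cur + timedelta(hours=hours)
            records.append(sleep_rec(stage, cur, end))
            cur = end
        df = aggregate_sleep(records)
        night = date(2024, 3, 4)
        assert df.loc[night, "sleep_total_s"] / 3600 == pytest.approx(7.26)
        assert df.loc[night, "core_s"] / 3600 == pytest.approx(4.98)

    def test_single_core_record(self):
        t0 = datetime(2024, 3, 4, 22, 0, tzinfo=TZ)
        df = aggregate_sleep([sleep_rec("core", t0, t0 + timedelta(hours=8))])
        night = date(2024, 3, 4)
        assert df.loc[night, "core_s"] == df.loc[night, "sleep_total_s"] == 8 * 3600

    def test_awake_only_night_has_zero_sums(self):
        t0 = datetime(2024, 3, 4, 23, 0, tzinfo=TZ)
        df = aggregate_sleep([sleep_rec("awake", t0, t0 + timedelta(hours=1))])
        night = date(2024, 3, 4)
        assert df.loc[night, "sleep_total_s"] == 0.0

    def test_overlapping_same_stage_merged_with_warning(self):
        t0 = datetime(2024, 3, 4, 23, 0, tzinfo=TZ)
        records = [
            sleep_rec("core", t0, t0 + timedelta(hours=2)),
            sleep_rec("core", t0 + timedelta(hours=1), t0 + timedelta(hours=3)),
        ]
        with pytest.warns(UserWarning, match="overlapping"):
            df = aggregate_sleep(records)
        assert df.iloc[0]["core_s"] == 3 * 3600  # merged, not 4 h

    def test_morning_records_assigned_to_previous_evening(self):
        t0 = datetime(2024, 3, 5, 2, 0, tzinfo=TZ)  # 02:00 belongs to Mar 4
        df = aggregate_sleep([sleep_rec("rem", t0, t0 + timedelta(hours=1))])
        assert df.index[0] == date(2024, 3, 4)


class TestTsuSuib:
    def test_tsu_passthrough(self):
        out = compute_tsu([DailyUsageTotal("p", date(2024, 3, 4), 13860.0)])
        assert out[date(2024, 3, 4)] / 3600 == pytest.approx(3.85)
        assert compute_tsu([DailyUsageTotal("p", date(2024, 3, 5), 0.0)])[
            date(2024, 3, 5)] == 0.0

    def interval(self, enter, exit_):
        return InBedInterval("p", enter, exit_, source_night=enter.date())

    def test_hour_fully_inside(self):
        iv = self.interval(datetime(2024, 3, 4, 23, 0, tzinfo=TZ),
                           datetime(2024, 3, 5, 7, 0, tzinfo=TZ))
        out = compute_suib([UsageHour("p", date(2024, 3, 5), 2, 1800)], [iv])
        assert out[date(2024, 3, 4)] == pytest.approx(1800)

    def test_half_covered_hour_prorated(self):
        iv = self.interval(datetime(2024, 3, 4, 23, 30, tzinfo=TZ),
                           datetime(2024, 3, 5, 7, 0, tzinfo=TZ))
        out = compute_suib([UsageHour("p", date(2024, 3, 4), 23, 600)], [iv])
        assert out[date(2024, 3, 4)] == pytest.approx(300)

    def test_boundary_hours_match_minute_rasterization(self):
        """Interval 23:30-07:00, 600 s in hour 23 and 900 s in hour 6."""
        iv = self.interval(datetime(2024, 3, 4, 23, 30, tzinfo=TZ),
                           datetime(2024, 3, 5, 7, 0, tzinfo=TZ))
        hours = [UsageHour("p", date(2024, 3, 4), 23, 600),
                 UsageHour("p", date(2024, 3, 5), 6, 900)]
        out = compute_suib(hours, [iv])

        # minute-level oracle: usage uniform over each clock hour
        total = 0.0
        for h in hours:
            start = datetime.combine(h.date, time(h.hour), tzinfo=TZ)
            for minute in range(60):
                t = start + timedelta(minutes=minute)
                if iv.enter <= t < iv.exit:
                    total += h.seconds_used / 60.0
        assert out[date(2024, 3, 4)] == pytest.approx(total) == pytest.approx(1200)

    def test_detected_night_without_usage_is_zero(self):
        iv = self.interval(datetime(2024, 3, 4, 23, 0, tzinfo=TZ),
                           datetime(2024, 3, 5, 7, 0, tzinfo=TZ))
        assert compute_suib([], [iv])[date(2024, 3, 4)] == 0.0

    def test_suib_capped_at_tsu_in_assembly(self):
        days = [date(2024, 3, 4)]
        out = assemble_panel("p", days, {days[0]: 1000.0}, {days[0]: 2500.0},
                             pd.DataFrame(columns=["rem_s", "core_s", "deep_s",
                                                   "sleep_total_s"]))
        assert out.loc[0, "suib_s"] == 1000.0

    def test_suib_missing_when_screen_time_missing(self):
        days = [date(2024, 3, 4)]
        out = assemble_panel("p", days, {}, {days[0]: 500.0},
                             pd.DataFrame(columns=["rem_s", "core_s", "deep_s",
                                                   "sleep_total_s"]))
        assert np.isnan(out.loc[0, "suib_s"])


def build_missingness_fixture(n_total=76, n_bad=8):
    """A 14-day panel where exactly `n_bad` participants have >= 7 missing
    days on sleep or screen time."""
    rows = []
    for i in range(n_total):
        pid = f"p{i:02d}"
        bad = i < n_bad
        for t in range(1, 15):
            missing = bad and t <= 7  # exactly 7 missing days
            rows.append({
                "participant_id": pid, "day_index": t,
                "date": date(2024, 3, 3 + t),
                "tsu_s": np.nan if (missing and i % 2 == 0) else 7200.0,
                "suib_s": 600.0,
                "sleep_total_s": np.nan if (missing and i % 2 == 1) else 26000.0,
                "rem_s": 5000.0, "core_s": 18000.0, "deep_s": 3000.0,
            })
    return pd.DataFrame(rows)


class TestFilterMissing:
    def test_76_minus_8_leaves_68(self):
        panel = build_missingness_fixture()
        kept, report = filter_missing(panel)
        assert kept["participant_id"].nunique() == 68
        assert len(report["excluded"]) == 8

    def test_exactly_seven_missing_is_excluded(self):
        """The rule is >= 7, so exactly 7 missing days excludes."""
        panel = build_missingness_fixture(n_total=1, n_bad=1)
        kept, report = filter_missing(panel)
        assert kept.empty
        assert report["excluded"][0]["missing_sleep_days"] in (0, 7)

    def test_complete_panel_unchanged(self, small_panel):
        kept, report = filter_missing(small_panel)
        assert len(kept) == len(small_panel)
        assert report["excluded"] == []

    def test_idempotent(self):
        panel = build_missingness_fixture()
        once, _ = filter_missing(panel)
        twice, _ = filter_missing(once)
        pd.testing.assert_frame_equal(once, twice)


class TestDecompose:
    def test_within_components_of_simple_series(self):
        from conftest import make_panel_from_series

        panel = make_panel_from_series({"a": [2.0, 4.0, 6.0], "b": [1.0, 1.0, 1.0]})
        dp = decompose(panel, variables=["tsu"], standardize=False)
        a = dp.data[dp.data.participant_id == "a"]
        np.testing.assert_allclose(a["w_tsu"], [-2.0, 0.0, 2.0])

    def test_constant_series_has_zero_within(self):
        from conftest import make_panel_from_series

        panel = make_panel_from_series({"a": [5.0] * 4, "b": [9.0] * 4})
        dp = decompose(panel, variables=["tsu"], standardize=False)
        a = dp.data[dp.data.participant_id == "a"]
        np.testing.assert_allclose(a["w_tsu"], 0.0, atol=1e-12)
        assert a["b_tsu"].iloc[0] == pytest.approx(5.0 - 7.0)

    def test_lag_row_count(self, small_panel):
        dp = decompose(small_panel)
        n = small_panel["participant_id"].nunique()
        complete = dp.data.dropna(subset=["w_tsu_lag"])
        assert len(complete) == n * 13

    def test_day_one_carries_missing_lags(self, small_panel):
        dp = decompose(small_panel)
        day1 = dp.data[dp.data.day_index == 1]
        assert day1["w_tsu_lag"].isna().all()

    def test_within_sums_to_zero_per_participant(self, small_panel):
        dp = decompose(small_panel, standardize=True)
        sums = dp.data.groupby("participant_id")["w_sleep_total"].sum()
        np.testing.assert_allclose(sums, 0.0, atol=1e-9)

    def test_exact_identity_on_observed_cells(self, holey_panel):
        """v(t) = grand_mean + between + within, exactly, where observed."""
        dp = decompose(holey_panel, standardize=False)
        merged = dp.data.merge(holey_panel, on=["participant_id", "day_index"])
        for v in ("tsu", "suib", "sleep_total"):
            recon = dp.grand_means[v] + merged[f"b_{v}"] + merged[f"w_{v}"]
            obs = merged[f"{v}_s"].notna()
            np.testing.assert_allclose(recon[obs], merged.loc[obs, f"{v}_s"],
                                       atol=1e-6)

    def test_lag_pairing_matches_bruteforce(self, small_panel):
        """Lagged columns pair day t with t-1 inside each participant only."""
        dp = decompose(small_panel, standardize=False)
        rng = np.random.default_rng(0)
        pids = rng.choice(small_panel["participant_id"].unique(), 5, replace=False)
        for pid in pids:
            raw = small_panel[small_panel.participant_id == pid].sort_values("day_index")
            got = dp.data[dp.data.participant_id == pid].sort_values("day_index")
            expected = raw["tsu_s"].shift(1) - raw["tsu_s"].mean()
            np.testing.assert_allclose(got["w_tsu_lag"].to_numpy()[1:],
                                       expected.to_numpy()[1:], atol=1e-9)

    def test_single_observation_participant_dropped(self):
        from conftest import make_panel_from_series

        panel = make_panel_from_series({"a": [2.0, 4.0, 6.0]})
        lonely = make_panel_from_series({"z": [1.0]})
        for c in ("tsu_s", "suib_s", "sleep_total_s", "rem_s", "core_s", "deep_s"):
            lonely[c] = [np.nan]
        with pytest.warns(UserWarning, match="<2 observed days"):
            dp = decompose(pd.concat([panel, lonely]), variables=["tsu"])
        assert "z" not in set(dp.data.participant_id)


class TestImpute:
    def test_complete_data_gives_identical_panels(self, small_panel):
        imps = impute(small_panel, m=3, seed=1)
        for comp in imps.completed[1:]:
            pd.testing.assert_frame_equal(comp, imps.completed[0])

    def test_observed_cells_untouched(self, holey_panel):
        imps = impute(holey_panel, m=2, seed=1)
        obs = holey_panel["tsu_s"].notna()
        for comp in imps.completed:
            np.testing.assert_allclose(comp.loc[obs, "tsu_s"],
                                       holey_panel.loc[obs, "tsu_s"])
            assert comp["tsu_s"].notna().all()

    def test_seed_reproducibility(self, holey_panel):
        a = impute(holey_panel, m=2, seed=9)
        b = impute(holey_panel, m=2, seed=9)
        for x, y in zip(a.completed, b.completed):
            pd.testing.assert_frame_equal(x, y)

    def test_imputed_values_vary_and_stay_in_range(self, holey_panel):
        """Across seeds, imputations vary and stay within the observed
        range widened by 3 SD."""
        cell = holey_panel["tsu_s"].isna()
        lo, hi = 0.0, np.nanmax(holey_panel["tsu_s"]) + 3 * np.nanstd(holey_panel["tsu_s"])
        values = []
        for seed in range(25):
            imps = impute(holey_panel, m=1, seed=seed)
            filled = imps.completed[0].loc[cell, "tsu_s"]
            assert ((filled >= lo) & (filled <= hi + 1e-6)).all()
            values.append(filled.to_numpy())
        spread = np.std(np.stack(values), axis=0)
        assert (spread > 0).all()

    def test_all_missing_column_rejected(self, small_panel):
        broken = small_panel.copy()
        broken["suib_s"] = np.nan
        with pytest.raises(ValueError, match="no observed values"):
            impute(broken, m=2, seed=0)
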