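"""Person-day panel construction and within/between decomposition.

The analysis panel has one row per participant per study day with six
variables, all in seconds: total smartphone use (TSU), smartphone use in
bed (SUiB), and total / REM / core / deep sleep. Nights are assigned to
the evening's calendar date, so the same-day ordering TSU (daytime) ->
SUiB (evening, in bed) -> sleep (night) is temporally coherent.

Each variable v is split into a between-person component (the person mean,
centered at the grand mean — stable habits) and a within-person component
(the day's deviation from the person's own mean — daily dynamics), with
lag-1 copies decomposed the same way. Standardization divides within
components by their pooled within-person SD and between components by the
SD of person means, which puts fitted coefficients on the standardized
beta scale.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .inbed import InBedInterval
from .io_ingest import (
    PANEL_COLUMNS,
    DailyUsageTotal,
    SleepStageRecord,
    UsageHour,
)

#: model-level variable names; panel columns append the ``_s`` unit suffix
ALL_VARIABLES = ["tsu", "suib", "sleep_total", "rem", "core", "deep"]
SLEEP_STAGES = ["rem", "core", "deep"]


def default_night_of(ts: datetime) -> date:
    """Clock rule assigning a timestamp to a night (the evening's date).

    Anything from noon onward belongs to that evening's night; anything
    before noon belongs to the previous evening's night.
    """
    return ts.date() if ts.time() >= time(12, 0) else ts.date() - timedelta(days=1)


def aggregate_sleep(
    sleep_records: Sequence[SleepStageRecord],
    night_of: Callable[[datetime], date] | None = None,
) -> pd.DataFrame:
    """Sum stage seconds per night for one participant.

    Awake episodes are excluded from sleep sums. Overlapping same-stage
    records are merged before summation (with a warning), so duplicated
    export rows cannot double-count sleep. Returns a frame indexed by
    night date with columns rem_s/core_s/deep_s/sleep_total_s; nights with
    only awake records appear with all-zero sums.
    """
    night_of = night_of or default_night_of
    by_key: dict[tuple[date, str], list[tuple[datetime, datetime]]] = {}
    nights_seen: set[date] = set()
    for rec in sleep_records:
        night = night_of(rec.start)
        nights_seen.add(night)
        if rec.stage.value == "awake":
            continue
        by_key.setdefault((night, rec.stage.value), []).append((rec.start, rec.end))
    rows: dict[date, dict[str, float]] = {
        n: {f"{s}_s": 0.0 for s in SLEEP_STAGES} for n in nights_seen
    }
    for (night, stage), spans in by_key.items():
        spans.sort()
        merged = [list(spans[0])]
        overlapped = False
        for s, e in spans[1:]:
            if s < merged[-1][1]:
                overlapped = True
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        if overlapped:
            _warnings.warn(
                f"overlapping {stage} records on night {night}; merged", stacklevel=2
            )
        rows[night][f"{stage}_s"] = sum((e - s).total_seconds() for s, e in merged)
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    if df.empty:
        df = pd.DataFrame(columns=[f"{s}_s" for s in SLEEP_STAGES])
    df["sleep_total_s"] = df[[f"{s}_s" for s in SLEEP_STAGES]].sum(axis=1)
    df.index.name = "date"
    return df


def compute_tsu(daily_totals: Iterable[DailyUsageTotal]) -> dict[date, float]:
    """Daily total smartphone use in seconds, validated pass-through."""
    out: dict[date, float] = {}
    for d in daily_totals:
        if d.seconds_used < 0:
            raise ValueError(f"negative daily total on {d.date}")
        out[d.date] = float(d.seconds_used)
    return out


def compute_suib(
    usage_hours: Iterable[UsageHour],
    inbed_intervals: Iterable[InBedInterval],
) -> dict[date, float]:
    """Smartphone-use-in-bed seconds per detected night.

    Screen time is only known per clock hour, so each hour's seconds are
    assumed uniform across that hour and prorated by its overlap with the
    in-bed interval. Nights with a detected interval but no overlapping
    usage get 0 (usage was simply elsewhere); undetected nights are absent
    from the result (missing).
    """
    by_hour: dict[tuple[date, int], float] = {}
    for h in usage_hours:
        by_hour[(h.date, h.hour)] = by_hour.get((h.date, h.hour), 0.0) + h.seconds_used
    out: dict[date, float] = {}
    for iv in inbed_intervals:
        total = 0.0
        tz = iv.enter.tzinfo
        hour_start = iv.enter.replace(minute=0, second=0, microsecond=0)
        while hour_start < iv.exit:
            hour_end = hour_start + timedelta(hours=1)
            overlap = (min(iv.exit, hour_end) - max(iv.enter, hour_start)).total_seconds()
            if overlap > 0:
                sec = by_hour.get((hour_start.date(), hour_start.hour), 0.0)
                total += sec * overlap / 3600.0
            hour_start = hour_end
        night = iv.source_night if iv.source_night is not None else iv.enter.date()
        out[night] = out.get(night, 0.0) + total
    return out


def assemble_panel(
    participant_id: str,
    study_days: Sequence[date],
    tsu: Mapping[date, float],
    suib: Mapping[date, float],
    sleep: pd.DataFrame,
) -> pd.DataFrame:
    """Join the per-day quantities into tidy panel rows for one participant.

    SUiB is capped at TSU when both are present (in-bed use is a subset of
    total use; hourly proration can overshoot the rounded daily total) and
    is missing whenever the day's screen-time source is missing — without
    the screenshot, zero observed in-bed usage is unobserved, not zero.
    """
    rows = []
    for t, day in enumerate(study_days, start=1):
        row = {"participant_id": participant_id, "day_index": t, "date": day}
        row["tsu_s"] = tsu.get(day, np.nan)
        row["suib_s"] = suib.get(day, np.nan) if day in tsu else np.nan
        if day in sleep.index:
            for c in ("rem_s", "core_s", "deep_s", "sleep_total_s"):
                row[c] = float(sleep.loc[day, c])
        else:
            for c in ("rem_s", "core_s", "deep_s", "sleep_total_s"):
                row[c] = np.nan
        if np.isfinite(row["suib_s"]) and np.isfinite(row["tsu_s"]):
            row["suib_s"] = min(row["suib_s"], row["tsu_s"])
        rows.append(row)
    return pd.DataFrame(rows)[PANEL_COLUMNS]


def filter_missing(
    panel: pd.DataFrame, max_missing_days: int = 7, n_days: int = 14
) -> tuple[pd.DataFrame, dict]:
    """Drop participants with heavy missingness; report who and why.

    A participant is excluded when sleep OR screen time is missing on at
    least ``max_missing_days`` of the ``n_days`` study days. Idempotent.
    """
    report: dict = {"excluded": [], "retained": 0, "rule": f">={max_missing_days} missing days"}
    keep = []
    for pid, grp in panel.groupby("participant_id", sort=True):
        sleep_missing = n_days - int(grp["sleep_total_s"].notna().sum())
        st_missing = n_days - int(grp["tsu_s"].notna().sum())
        causes = []
        if sleep_missing >= max_missing_days:
            causes.append("sleep")
        if st_missing >= max_missing_days:
            causes.append("screen_time")
        if causes:
            report["excluded"].append(
                {"participant_id": pid, "causes": causes,
                 "missing_sleep_days": sleep_missing, "missing_st_days": st_missing}
            )
        else:
            keep.append(pid)
    out = panel[panel["participant_id"].isin(keep)].reset_index(drop=True)
    report["retained"] = len(keep)
    return out, report


@dataclass
class DecomposedPanel:
    """Lagged, centered, standardized design quantities for the DSEM.

    ``data`` has one row per person-day with, for each variable v:
    ``w_<v>`` (within deviation), ``b_<v>`` (between component from the
    current-series person mean), ``w_<v>_lag`` and ``b_<v>_lag`` (lag-1
    copies; between from the lagged-series mean, i.e. days 1..T-1).
    Day-1 rows carry missing lags. Scale dictionaries record the SDs used
    so estimates can be mapped back to seconds.
    """

    data: pd.DataFrame
    variables: list[str]
    grand_means: dict[str, float]
    within_sd: dict[str, float]
    between_sd: dict[str, float]
    total_sd: dict[str, float]
    standardized: bool = True
    person_means: pd.DataFrame | None = None


def decompose(
    panel: pd.DataFrame,
    variables: Sequence[str] | None = None,
    standardize: bool = True,
    reference: pd.DataFrame | None = None,
) -> DecomposedPanel:
    """Split each variable into within/between components with lag-1 copies.

    Person means come from ``reference`` (default: the panel itself) so
    that centering can be anchored on observed rather than imputed days.
    Lags never cross participants. Participants with fewer than two
    observed days cannot be lagged and are dropped with a warning.
    """
    variables = list(variables or ALL_VARIABLES)
    ref = panel if reference is None else reference
    panel = panel.sort_values(["participant_id", "day_index"]).reset_index(drop=True)

    ok_pids = []
    for pid, grp in ref.groupby("participant_id"):
        if int(grp[[f"{v}_s" for v in variables]].notna().any(axis=1).sum()) >= 2:
            ok_pids.append(pid)
        else:
            _warnings.warn(f"participant {pid} has <2 observed days; dropped",
                           stacklevel=2)
    panel = panel[panel["participant_id"].isin(ok_pids)]

    out = panel[["participant_id", "day_index", "date"]].copy()
    g = panel.groupby("participant_id")
    pm_rows = {}
    grand_means: dict[str, float] = {}
    within_sd: dict[str, float] = {}
    between_sd: dict[str, float] = {}
    total_sd: dict[str, float] = {}
    ref_g = ref[ref["participant_id"].isin(ok_pids)].groupby("participant_id")
    for v in variables:
        col = f"{v}_s"
        pm_all = ref_g[col].mean()  # observed-day person mean (NaN-aware)
        lag = panel[panel["day_index"] <= panel.groupby("participant_id")["day_index"].transform("max") - 1]
        pm_lag = lag.groupby("participant_id")[col].mean()
        pm_rows[v] = pm_all

        pm_of = panel["participant_id"].map(pm_all)
        w = panel[col].to_numpy() - pm_of.to_numpy()
        lag_vals = g[col].shift(1)
        w_lag = lag_vals.to_numpy() - pm_of.to_numpy()

        # current-timing between component: all-observed-days person mean,
        # so v(t) = grand_mean + between + within holds exactly; lagged
        # between predictors use the lagged-series (days 1..T-1) means
        gm_all = float(pm_all.mean())
        gm_lag = float(pm_lag.mean())
        b = pm_of.to_numpy() - gm_all
        b_lag = panel["participant_id"].map(pm_lag).to_numpy() - gm_lag
        grand_means[v] = gm_all

        sd_w = float(np.nanstd(w, ddof=1))
        sd_w_lag = float(np.nanstd(w_lag[panel["day_index"].to_numpy() >= 2], ddof=1))
        sd_b = float(np.nanstd(pm_all.to_numpy(), ddof=1))
        sd_b_lag = float(np.nanstd(pm_lag.to_numpy(), ddof=1))
        within_sd[v] = sd_w
        between_sd[v] = sd_b
        total_sd[v] = float(np.nanstd(panel[col].to_numpy(dtype=float), ddof=1))
        if standardize:
            w = w / sd_w if sd_w > 0 else w
            w_lag = w_lag / sd_w_lag if sd_w_lag > 0 else w_lag
            b = b / sd_b if sd_b > 0 else b
            b_lag = b_lag / sd_b_lag if sd_b_lag > 0 else b_lag
        out[f"w_{v}"] = w
        out[f"b_{v}"] = b
        out[f"w_{v}_lag"] = w_lag
        out[f"b_{v}_lag"] = b_lag

    return DecomposedPanel(
        data=out.reset_index(drop=True),
        variables=variables,
        grand_means=grand_means,
        within_sd=within_sd,
        between_sd=between_sd,
        total_sd=total_sd,
        standardized=standardize,
        person_means=pd.DataFrame(pm_rows),
    )


@dataclass
class ImputationSet:
    """``m`` completed panels (and their decompositions) from one seed."""

    completed: list[pd.DataFrame]
    decomposed: list[DecomposedPanel]
    seed: int
    method: str = "chained-equations"

    @property
    def m(self) -> int:
        return len(self.completed)


def impute(
    panel: pd.DataFrame,
    m: int = 5,
    seed: int = 0,
    variables: Sequence[str] | None = None,
) -> ImputationSet:
    """Multiply impute missing person-day cells by chained equations.

    Predictors are the same-day other variables, observed-day person means
    of every variable, and day-of-week indicators. Each of the ``m``
    completed panels is drawn with ``sample_posterior=True`` under a
    distinct stream of the given seed, then decomposed with centering
    anchored on observed-day person means. Observed cells are never
    modified. A variable with zero observed values cannot be imputed.
    """
    variables = list(variables or ALL_VARIABLES)
    cols = [f"{v}_s" for v in variables]
    panel = panel.sort_values(["participant_id", "day_index"]).reset_index(drop=True)
    for c in cols:
        if panel[c].notna().sum() == 0:
            raise ValueError(f"column {c} has no observed values; cannot impute")

    X = panel[cols].to_numpy(dtype=float)
    pm = panel.groupby("participant_id")[cols].transform("mean").to_numpy()
    pm = np.where(np.isfinite(pm), pm, np.nanmean(X, axis=0))
    dow = pd.to_datetime(panel["date"]).dt.dayofweek.to_numpy()
    dow_onehot = np.eye(7)[dow][:, :6]
    extras = np.hstack([pm, dow_onehot])

    lo = np.zeros(X.shape[1])
    hi = np.nanmax(X, axis=0) + 3 * np.nanstd(X, axis=0)
    completed_panels: list[pd.DataFrame] = []
    decomposed: list[DecomposedPanel] = []
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=m)
    any_missing = np.isnan(X).any()
    for k in range(m):
        if any_missing:
            imp = IterativeImputer(
                sample_posterior=True,
                random_state=int(sub_seeds[k]),
                max_iter=10,
                min_value=np.concatenate([lo, np.full(extras.shape[1], -np.inf)]),
                max_value=np.concatenate([hi, np.full(extras.shape[1], np.inf)]),
            )
            filled = imp.fit_transform(np.hstack([X, extras]))[:, : X.shape[1]]
            filled[~np.isnan(X)] = X[~np.isnan(X)]
        else:
            filled = X.copy()
        comp = panel.copy()
        comp[cols] = filled
        if "sleep_total_s" in cols and all(f"{s}_s" in cols for s in SLEEP_STAGES):
            # keep the accounting identity on imputed rows
            stage_sum = comp[[f"{s}_s" for s in SLEEP_STAGES]].sum(axis=1)
            was_missing = np.isnan(panel["sleep_total_s"].to_numpy())
            comp.loc[was_missing, "sleep_total_s"] = stage_sum[was_missing]
        completed_panels.append(comp)
        decomposed.append(
            decompose(comp, variables=variables, standardize=True, reference=panel)
        )
    return ImputationSet(completed_panels, decomposed, seed=seed)


class PanelDecomposer(BaseEstimator):
    """Transformer wrapper around :func:`decompose`."""

    def __init__(self, variables=None, standardize=True):
        self.variables = variables
        self.standardize = standardize

    def fit(self, panel: pd.DataFrame, y=None):
        self.reference_ = panel
        return self

    def transform(self, panel: pd.DataFrame) -> DecomposedPanel:
        ref = getattr(self, "reference_", None)
        return decompose(panel, variables=self.variables,
                         standardize=self.standardize, reference=ref)

    def fit_transform(self, panel: pd.DataFrame, y=None) -> DecomposedPanel:
        return self.fit(panel).transform(panel)


class PanelImputer(BaseEstimator):
    """Estimator wrapper around :func:`impute` (m completed panels)."""

    def __init__(self, m=5, seed=0, variables=None):
        self.m = m
        self.seed = seed
        self.variables = variables

    def fit(self, panel: pd.DataFrame, y=None):
        self.imputations_ = impute(panel, m=self.m, seed=self.seed,
                                   variables=self.variables)
        return self

    def transform(self, panel: pd.DataFrame = None) -> ImputationSet:
        return self.imputations_

    def fit_transform(self, panel: pd.DataFrame, y=None) -> ImputationSet:
        return self.fit(panel).transform(panel)
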