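"""Nightly in-bed interval detection from wrist step counts.

The watch does not export bed times; they are reconstructed from the step
counter. Step records are rasterized onto a regular epoch grid (default
10 min) and, within a nightly search window (default 20:00 to 12:00 the next
day), the longest sustained low-activity run is taken as the in-bed period.
Brief interior activity bursts are absorbed as wake-after-sleep-onset
(WASO); a sustained burst of activity confirms a bed exit and terminates the
interval. Recording gaps count as inactivity — a long gap is exactly what a
watch left on the nightstand, or a still sleeper, produces — but a night
with no coverage at all yields no interval and is flagged missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .io_ingest import StepRecord


@dataclass
class EpochSeries:
    """Step counts on a regular epoch grid for one participant.

    ``steps`` is NaN where the device had no coverage (missing is not zero).
    """

    participant_id: str
    epoch_start: datetime
    epoch_minutes: int
    steps: np.ndarray

    def time_of(self, i: int) -> datetime:
        return self.epoch_start + timedelta(minutes=self.epoch_minutes * i)

    def index_of(self, ts: datetime) -> float:
        return (ts - self.epoch_start).total_seconds() / (60 * self.epoch_minutes)


@dataclass
class InBedInterval:
    """One inferred nightly in-bed period with embedded WASO sub-intervals."""

    participant_id: str
    enter: datetime
    exit: datetime
    waso: list[tuple[datetime, datetime]] = field(default_factory=list)
    source_night: date | None = None

    def __post_init__(self):
        if self.exit <= self.enter:
            raise ValueError("in-bed exit must be after enter")
        prev_end = None
        for s, e in self.waso:
            if not (self.enter <= s < e <= self.exit):
                raise ValueError("WASO sub-interval outside in-bed interval")
            if prev_end is not None and s < prev_end:
                raise ValueError("WASO sub-intervals overlap")
            prev_end = e

    @property
    def duration_s(self) -> float:
        return (self.exit - self.enter).total_seconds()

    @property
    def waso_s(self) -> float:
        return sum((e - s).total_seconds() for s, e in self.waso)


@dataclass
class DetectorParams:
    """Thresholds of the in-bed classifier.

    epoch_minutes: grid resolution for step rasterization.
    low_step_threshold: steps/epoch strictly below which an epoch counts
        as inactive.
    window_start / window_end: clock times bounding the nightly search;
        the window spans midnight.
    min_inbed_hours: shortest run accepted as an in-bed period.
    max_waso_epochs: longest interior activity burst still absorbed as WASO.
    confirm_exit_epochs: consecutive active epochs that confirm a bed exit
        (takes precedence over WASO absorption on ties).
    """

    epoch_minutes: int = 10
    low_step_threshold: float = 5.0
    window_start: time = time(20, 0)
    window_end: time = time(12, 0)
    min_inbed_hours: float = 3.0
    max_waso_epochs: int = 3
    confirm_exit_epochs: int = 3

    def __post_init__(self):
        if self.epoch_minutes <= 0 or self.low_step_threshold <= 0:
            raise ValueError("epoch_minutes and low_step_threshold must be > 0")
        if self.min_inbed_hours <= 0:
            raise ValueError("min_inbed_hours must be > 0")
        if self.max_waso_epochs < 0 or self.confirm_exit_epochs < 1:
            raise ValueError("invalid burst thresholds")
        if self.window_start <= self.window_end:
            raise ValueError("nightly window must span midnight")


def epoch_steps(
    step_records: Sequence[StepRecord], params: DetectorParams | None = None
) -> EpochSeries:
    """Rasterize step records for one participant onto the epoch grid.

    Each record's steps are apportioned to epochs proportionally to
    temporal overlap; overlapping records sum. Epochs never touched by any
    record are missing (NaN), not zero — a record of zero steps is
    evidence of stillness, no record is no evidence.
    """
    params = params or DetectorParams()
    if not step_records:
        raise ValueError("no step records")
    pids = {r.participant_id for r in step_records}
    if len(pids) > 1:
        raise ValueError(f"records from multiple participants: {sorted(pids)}")
    epoch_s = params.epoch_minutes * 60
    t0 = min(r.start for r in step_records)
    t0 = t0.replace(minute=(t0.minute // params.epoch_minutes) * params.epoch_minutes,
                    second=0, microsecond=0)
    t1 = max(r.end for r in step_records)
    n = int(np.ceil(max((t1 - t0).total_seconds(), 1) / epoch_s))
    steps = np.full(n, np.nan)
    for rec in step_records:
        lo = (rec.start - t0).total_seconds() / epoch_s
        hi = (rec.end - t0).total_seconds() / epoch_s
        if hi == lo:  # instantaneous record: all steps to its epoch
            i = min(int(lo), n - 1)
            steps[i] = (0.0 if np.isnan(steps[i]) else steps[i]) + rec.steps
            continue
        for i in range(int(np.floor(lo)), min(int(np.ceil(hi)), n)):
            overlap = min(hi, i + 1) - max(lo, i)
            if overlap <= 0:
                continue
            frac = overlap / (hi - lo)
            steps[i] = (0.0 if np.isnan(steps[i]) else steps[i]) + rec.steps * frac
    return EpochSeries(step_records[0].participant_id, t0, params.epoch_minutes, steps)


def _classify(steps: np.ndarray, threshold: float) -> np.ndarray:
    """Per-epoch code: 0 = inactive (low steps or recording gap), 1 = active."""
    active = np.zeros(len(steps), dtype=int)
    obs = ~np.isnan(steps)
    active[obs & (steps >= threshold)] = 1
    return active


def _candidate_runs(codes: np.ndarray, params: DetectorParams):
    """All maximal in-bed candidate runs in a coded epoch string.

    A run starts and ends on an inactive epoch. Interior activity bursts
    strictly shorter than ``confirm_exit_epochs`` and no longer than
    ``max_waso_epochs`` are absorbed as WASO; any longer burst splits runs.
    Yields (start_idx, end_idx_exclusive, waso_bursts) tuples.
    """
    n = len(codes)
    absorb = min(params.max_waso_epochs, params.confirm_exit_epochs - 1)
    i = 0
    while i < n:
        if codes[i] == 1:
            i += 1
            continue
        start = i
        waso: list[tuple[int, int]] = []
        j = i
        while j < n:
            if codes[j] == 0:
                j += 1
                continue
            k = j
            while k < n and codes[k] == 1:
                k += 1
            burst = k - j
            if burst <= absorb and k < n:  # absorbed only if sleep resumes
                waso.append((j, k))
                j = k
            else:
                break
        yield start, j, waso
        i = max(j, i + 1)
        while i < n and codes[i] == 1:
            i += 1


def detect_inbed(
    epochs: EpochSeries, params: DetectorParams | None = None
) -> tuple[list[InBedInterval], list[date]]:
    """Detect at most one in-bed interval per nightly window.

    Returns the detected intervals and the list of nights (evening dates)
    that had a window but no usable data or no qualifying run. Within each
    window the longest qualifying run wins; ties go to the earliest.
    """
    params = params or DetectorParams()
    codes = _classify(epochs.steps, params.low_step_threshold)
    missing = np.isnan(epochs.steps)
    n = len(codes)
    end_time = epochs.time_of(n)

    intervals: list[InBedInterval] = []
    flagged: list[date] = []
    night = (epochs.epoch_start - timedelta(hours=12)).date()
    while True:
        w_start = datetime.combine(night, params.window_start,
                                   tzinfo=epochs.epoch_start.tzinfo)
        w_end = datetime.combine(night + timedelta(days=1), params.window_end,
                                 tzinfo=epochs.epoch_start.tzinfo)
        if w_start >= end_time:
            break
        night_date = night
        night += timedelta(days=1)
        lo = max(int(np.floor(epochs.index_of(w_start))), 0)
        hi = min(int(np.ceil(epochs.index_of(w_end))), n)
        if hi <= lo:
            continue
        window = codes[lo:hi]
        if missing[lo:hi].all():
            flagged.append(night_date)
            continue
        best = None
        min_epochs = params.min_inbed_hours * 60 / params.epoch_minutes
        for s, e, waso in _candidate_runs(window, params):
            if e - s < min_epochs:
                continue
            if best is None or (e - s) > (best[1] - best[0]):
                best = (s, e, waso)
        if best is None:
            flagged.append(night_date)
            continue
        s, e, waso = best
        intervals.append(
            InBedInterval(
                epochs.participant_id,
                enter=epochs.time_of(lo + s),
                exit=epochs.time_of(lo + e),
                waso=[(epochs.time_of(lo + a), epochs.time_of(lo + b))
                      for a, b in waso],
                source_night=night_date,
            )
        )
    return intervals, flagged


def inbed_coverage(
    intervals: Iterable[InBedInterval], study_days: Sequence[date]
) -> dict[date, bool]:
    """Per-night presence flag consumed by the missingness filter."""
    nights = {iv.source_night for iv in intervals}
    return {d: d in nights for d in study_days}


class InBedDetector(BaseEstimator):
    """Estimator-style wrapper around the in-bed classifier.

    Parameters mirror :class:`DetectorParams`; ``transform`` maps a list of
    step records to the detected intervals and sets ``flagged_nights_``.
    """

    def __init__(self, epoch_minutes=10, low_step_threshold=5.0,
                 window_start=time(20, 0), window_end=time(12, 0),
                 min_inbed_hours=3.0, max_waso_epochs=3, confirm_exit_epochs=3):
        self.epoch_minutes = epoch_minutes
        self.low_step_threshold = low_step_threshold
        self.window_start = window_start
        self.window_end = window_end
        self.min_inbed_hours = min_inbed_hours
        self.max_waso_epochs = max_waso_epochs
        self.confirm_exit_epochs = confirm_exit_epochs

    def _params(self) -> DetectorParams:
        return DetectorParams(
            epoch_minutes=self.epoch_minutes,
            low_step_threshold=self.low_step_threshold,
            window_start=self.window_start,
            window_end=self.window_end,
            min_inbed_hours=self.min_inbed_hours,
            max_waso_epochs=self.max_waso_epochs,
            confirm_exit_epochs=self.confirm_exit_epochs,
        )

    def fit(self, X=None, y=None):
        self.params_ = self._params()
        return self

    def transform(self, step_records: Sequence[StepRecord]) -> list[InBedInterval]:
        params = self._params()
        series = epoch_steps(step_records, params)
        intervals, flagged = detect_inbed(series, params)
        self.flagged_nights_ = flagged
        return intervals
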