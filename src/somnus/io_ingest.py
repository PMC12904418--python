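"""Readers for the raw study inputs and the tidy panel interchange format.

Two raw sources feed the pipeline: a HealthKit-export-style XML file from the
watch (sleep-stage episodes and step counts) and a hand-coded screen-time CSV
(daily totals plus hourly usage seconds). Both are pseudonymized on ingest.
All timestamps are converted to a single configured study timezone because
nightly in-bed windows are defined in local clock time.
"""

from __future__ import annotations

import hashlib
import hmac
import io
from dataclasses import dataclass, field
from datetime import date, datetime
from enum import Enum
from typing import IO, Iterable, Mapping
from zoneinfo import ZoneInfo

import pandas as pd
from lxml import etree

DEFAULT_TIMEZONE = "Europe/Brussels"

SLEEP_TYPE = "HKCategoryTypeIdentifierSleepAnalysis"
STEP_TYPE = "HKQuantityTypeIdentifierStepCount"

#: HealthKit sleep-analysis value vocabulary -> stage enum. watchOS >= 9
#: exports stage-resolved values; older exports use plain "Asleep"/"InBed".
#: Unstaged "Asleep" is binned with core (N1/N2, the default stage); "InBed"
#: is not sleep and is skipped (counted in warnings).
_STAGE_MAP = {
    "HKCategoryValueSleepAnalysisAwake": "awake",
    "HKCategoryValueSleepAnalysisAsleepREM": "rem",
    "HKCategoryValueSleepAnalysisAsleepCore": "core",
    "HKCategoryValueSleepAnalysisAsleepDeep": "deep",
    "HKCategoryValueSleepAnalysisAsleep": "core",
    "Awake": "awake",
    "REM": "rem",
    "Core": "core",
    "Deep": "deep",
    "Asleep": "core",
}
_SKIP_VALUES = {"HKCategoryValueSleepAnalysisInBed", "InBed"}

PANEL_COLUMNS = [
    "participant_id",
    "day_index",
    "date",
    "tsu_s",
    "suib_s",
    "sleep_total_s",
    "rem_s",
    "core_s",
    "deep_s",
]


class SleepStage(str, Enum):
    AWAKE = "awake"
    REM = "rem"
    CORE = "core"
    DEEP = "deep"


class IngestError(ValueError):
    """Raised on malformed or invalid input."""


@dataclass(frozen=True)
class SleepStageRecord:
    """One timestamped sleep-stage episode from the watch export."""

    participant_id: str
    stage: SleepStage
    start: datetime
    end: datetime

    def __post_init__(self):
        if self.end <= self.start:
            raise IngestError(
                f"sleep record end {self.end} not after start {self.start}"
            )


@dataclass(frozen=True)
class StepRecord:
    """One step-count record (steps accumulated over [start, end])."""

    participant_id: str
    start: datetime
    end: datetime
    steps: float

    def __post_init__(self):
        if self.end < self.start:
            raise IngestError(f"step record end {self.end} before start {self.start}")
        if self.steps < 0:
            raise IngestError(f"negative step count {self.steps}")


@dataclass(frozen=True)
class UsageHour:
    """Screen-time seconds within one clock hour of one day."""

    participant_id: str
    date: date
    hour: int
    seconds_used: float

    def __post_init__(self):
        if not 0 <= self.hour <= 23:
            raise IngestError(f"hour {self.hour} outside 0-23")
        if not 0 <= self.seconds_used <= 3600:
            raise IngestError(f"hourly seconds {self.seconds_used} outside 0-3600")


@dataclass(frozen=True)
class DailyUsageTotal:
    """Total screen-time seconds reported for one day."""

    participant_id: str
    date: date
    seconds_used: float

    def __post_init__(self):
        if self.seconds_used < 0:
            raise IngestError(f"negative daily seconds {self.seconds_used}")


@dataclass
class IngestWarnings:
    """Counters for records skipped or flagged during ingest."""

    unknown_stage: int = 0
    skipped_type: int = 0
    out_of_window: int = 0
    inconsistent_daily: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "unknown_stage": self.unknown_stage,
            "skipped_type": self.skipped_type,
            "out_of_window": self.out_of_window,
            "inconsistent_daily": list(self.inconsistent_daily),
        }


def _parse_hk_timestamp(text: str, tz: ZoneInfo) -> datetime:
    # HealthKit exports "2024-03-01 23:10:00 +0100"; embedded offsets are
    # honoured, then everything is expressed in the study timezone.
    dt = datetime.strptime(text, "%Y-%m-%d %H:%M:%S %z")
    return dt.astimezone(tz)


def _iter_records(stream: IO) -> Iterable:
    try:
        for _, elem in etree.iterparse(stream, tag="Record"):
            yield elem
            elem.clear()
    except etree.XMLSyntaxError as exc:
        raise IngestError(
            f"malformed XML at line {exc.lineno}, column {exc.position[1]}: {exc.msg}"
        ) from exc


def _apply_id(raw_id: str, id_map: Mapping[str, str] | None) -> str:
    if id_map is None:
        return raw_id
    return id_map[raw_id] if raw_id in id_map else raw_id


def read_sleep_xml(
    stream: IO,
    id_map: Mapping[str, str] | None = None,
    *,
    timezone: str = DEFAULT_TIMEZONE,
    study_start: datetime | None = None,
    study_end: datetime | None = None,
    participant_attr: str = "sourceName",
    warnings: IngestWarnings | None = None,
) -> list[SleepStageRecord]:
    """Read sleep-analysis records from a HealthKit-style XML export.

    Only sleep-analysis ``Record`` elements are returned; every other record
    type (heart rate, noise exposure, steps, ...) is skipped and counted.
    Records outside the configured study window ``[study_start, study_end)``
    are dropped. Awake episodes are retained — they are excluded later when
    sleep durations are summed.
    """
    tz = ZoneInfo(timezone)
    warn = warnings if warnings is not None else IngestWarnings()
    out: list[SleepStageRecord] = []
    for elem in _iter_records(stream):
        if elem.get("type") != SLEEP_TYPE:
            warn.skipped_type += 1
            continue
        value = elem.get("value", "")
        if value in _SKIP_VALUES:
            warn.unknown_stage += 1
            continue
        stage = _STAGE_MAP.get(value)
        if stage is None:
            warn.unknown_stage += 1
            continue
        start = _parse_hk_timestamp(elem.get("startDate"), tz)
        end = _parse_hk_timestamp(elem.get("endDate"), tz)
        if not _in_window(start, study_start, study_end):
            warn.out_of_window += 1
            continue
        pid = _apply_id(elem.get(participant_attr, "unknown"), id_map)
        out.append(SleepStageRecord(pid, SleepStage(stage), start, end))
    return out


def read_steps_xml(
    stream: IO,
    id_map: Mapping[str, str] | None = None,
    *,
    timezone: str = DEFAULT_TIMEZONE,
    study_start: datetime | None = None,
    study_end: datetime | None = None,
    participant_attr: str = "sourceName",
    warnings: IngestWarnings | None = None,
) -> list[StepRecord]:
    """Read step-count records from a HealthKit-style XML export.

    Overlapping records are both kept; overlap resolution happens at
    epoching time. A negative count raises :class:`IngestError`.
    """
    tz = ZoneInfo(timezone)
    warn = warnings if warnings is not None else IngestWarnings()
    out: list[StepRecord] = []
    for elem in _iter_records(stream):
        if elem.get("type") != STEP_TYPE:
            warn.skipped_type += 1
            continue
        start = _parse_hk_timestamp(elem.get("startDate"), tz)
        end = _parse_hk_timestamp(elem.get("endDate"), tz)
        if not _in_window(start, study_start, study_end):
            warn.out_of_window += 1
            continue
        pid = _apply_id(elem.get(participant_attr, "unknown"), id_map)
        out.append(StepRecord(pid, start, end, float(elem.get("value"))))
    return out


def _in_window(ts: datetime, start: datetime | None, end: datetime | None) -> bool:
    # closed on the left, open on the right
    if start is not None and ts < start:
        return False
    if end is not None and ts >= end:
        return False
    return True


def read_usage_table(
    source: IO | str,
    id_map: Mapping[str, str] | None = None,
    *,
    warnings: IngestWarnings | None = None,
) -> tuple[list[UsageHour], list[DailyUsageTotal]]:
    """Read the hand-coded screen-time table.

    Expected columns: ``participant, date, hour, seconds`` with
    ``hour == "daily"`` marking daily-total rows. Duplicate
    (participant, date, hour) keys and hourly values above 3600 s are
    errors. Because daily totals were read off rounded screenshots, an
    hourly sum exceeding the daily total by more than 5% is flagged (not
    an error).
    """
    warn = warnings if warnings is not None else IngestWarnings()
    df = pd.read_csv(source, dtype={"participant": str, "hour": str})
    required = {"participant", "date", "hour", "seconds"}
    if not required.issubset(df.columns):
        raise IngestError(f"usage table missing columns {required - set(df.columns)}")
    dup = df.duplicated(subset=["participant", "date", "hour"])
    if dup.any():
        row = df[dup].iloc[0]
        raise IngestError(
            f"duplicate usage key ({row['participant']}, {row['date']}, {row['hour']})"
        )
    hours: list[UsageHour] = []
    dailies: list[DailyUsageTotal] = []
    for _, row in df.iterrows():
        pid = _apply_id(str(row["participant"]), id_map)
        day = pd.Timestamp(row["date"]).date()
        sec = float(row["seconds"])
        if str(row["hour"]).strip().lower() == "daily":
            dailies.append(DailyUsageTotal(pid, day, sec))
        else:
            hours.append(UsageHour(pid, day, int(row["hour"]), sec))
    hourly_sums: dict[tuple[str, date], float] = {}
    for h in hours:
        key = (h.participant_id, h.date)
        hourly_sums[key] = hourly_sums.get(key, 0.0) + h.seconds_used
    for d in dailies:
        s = hourly_sums.get((d.participant_id, d.date))
        if s is not None and s > d.seconds_used * 1.05:
            warn.inconsistent_daily.append(
                {"participant_id": d.participant_id, "date": str(d.date),
                 "hourly_sum": s, "daily_total": d.seconds_used}
            )
    return hours, dailies


def pseudonymize_id(raw_id: str, salt: str) -> str:
    """Deterministic opaque pseudonym for one identifier under a salt."""
    digest = hmac.new(salt.encode(), raw_id.encode(), hashlib.sha256).hexdigest()
    return "p" + digest[:12]


def pseudonymize(records: Iterable, salt: str) -> list:
    """Replace ``participant_id`` on each record with a salted pseudonym.

    The mapping is deterministic per salt and injective in practice
    (HMAC-SHA256 truncated to 48 bits of hex); original identifiers do not
    appear in the output.
    """
    import dataclasses

    out = []
    for rec in records:
        out.append(
            dataclasses.replace(
                rec, participant_id=pseudonymize_id(rec.participant_id, salt)
            )
        )
    return out


def write_panel(panel: pd.DataFrame, path_or_buf) -> None:
    """Write the tidy person-day panel CSV (ISO dates, seconds as integers)."""
    df = panel.copy()
    df = df[PANEL_COLUMNS]
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    for col in PANEL_COLUMNS[3:]:
        df[col] = df[col].round().astype("Int64")
    df.to_csv(path_or_buf, index=False, lineterminator="\n")


def read_panel(path_or_buf) -> pd.DataFrame:
    """Read a tidy panel CSV written by :func:`write_panel`."""
    df = pd.read_csv(path_or_buf, dtype={"participant_id": str})
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise IngestError(f"panel missing columns {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    df["day_index"] = df["day_index"].astype(int)
    for col in PANEL_COLUMNS[3:]:
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    return df[PANEL_COLUMNS]


def panel_roundtrip_bytes(panel: pd.DataFrame) -> bytes:
    """Canonical serialized form of a panel (used for manifest hashing)."""
    buf = io.StringIO()
    write_panel(panel, buf)
    return buf.getvalue().encode()
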