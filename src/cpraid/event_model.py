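"""Resuscitation event-log model and file formats.

Each simulated resuscitation is recorded as a timestamped event log: when the
team arrived at the patient, when chest compressions ran, when the heart rhythm
was checked, and when defibrillations, drug administrations and compressor
changes happened.  All timestamps are seconds from scenario start (t = 0 is
scenario start, not team arrival); intervals are half-open ``[start, end)``.

On disk a log is a single self-contained delimited file: ``# key=value`` header
lines carrying the team metadata, then a ``kind,timestamp_s`` table, one row
per event.  A cohort is described by a manifest table mapping team ids to event
files, optional compression-sample files, group labels and exclusion flags.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "Group",
    "EventKind",
    "Event",
    "EventLog",
    "CompressionSeries",
    "Violation",
    "LogParseError",
    "LogValidationError",
    "validate_log",
    "read_event_log",
    "write_event_log",
    "read_compression_series",
    "write_compression_series",
    "read_manifest",
    "write_manifest",
    "load_cohort",
]


class Group(str, enum.Enum):
    """Study arm: cognitive-aid app vs. no app."""

    CA_APP = "CA_APP"
    NO_APP = "NO_APP"


class EventKind(str, enum.Enum):
    COMPRESSIONS_START = "COMPRESSIONS_START"
    COMPRESSIONS_STOP = "COMPRESSIONS_STOP"
    RHYTHM_CHECK_START = "RHYTHM_CHECK_START"
    RHYTHM_CHECK_END = "RHYTHM_CHECK_END"
    DEFIBRILLATION = "DEFIBRILLATION"
    ADRENALINE = "ADRENALINE"
    AMIODARONE = "AMIODARONE"
    COMPRESSOR_CHANGE = "COMPRESSOR_CHANGE"
    ROSC = "ROSC"


@dataclass(frozen=True)
class Event:
    """One timestamped occurrence in a resuscitation.

    Defibrillations, drug administrations and compressor changes are point
    events; compressions and rhythm checks are coded as start/end pairs.
    """

    kind: EventKind
    timestamp: float

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise ValueError(f"event timestamp must be >= 0, got {self.timestamp}")


@dataclass(frozen=True)
class EventLog:
    """One team's complete coded scenario record."""

    team_id: str
    group: Group
    arrival_time: float
    scenario_end: float
    events: tuple[Event, ...]
    excluded: bool = False
    exclusion_reason: str = ""
    rosc_time: Optional[float] = None

    def events_of(self, kind: EventKind) -> list[Event]:
        return [e for e in self.events if e.kind == kind]

    def timestamps_of(self, kind: EventKind) -> list[float]:
        return [e.timestamp for e in self.events if e.kind == kind]

    def shifted(self, dt: float) -> "EventLog":
        """Translate the whole log by ``dt`` seconds (dt >= -min timestamp)."""
        return replace(
            self,
            arrival_time=self.arrival_time + dt,
            scenario_end=self.scenario_end + dt,
            rosc_time=None if self.rosc_time is None else self.rosc_time + dt,
            events=tuple(Event(e.kind, e.timestamp + dt) for e in self.events),
        )


@dataclass(frozen=True)
class CompressionSeries:
    """Per-period compression quality exported by the simulator software.

    ``samples`` are ``(period_start_s, period_end_s, mean_depth_cm,
    mean_rate_per_min)`` tuples over non-overlapping periods.  ``available``
    is False when the recording failed (a real failure mode of the study
    hardware); an unavailable series carries no samples.
    """

    team_id: str
    samples: tuple[tuple[float, float, float, float], ...] = ()
    available: bool = True

    def __post_init__(self) -> None:
        prev_end = -math.inf
        for start, end, depth, rate in self.samples:
            if end <= start:
                raise ValueError(f"empty compression period [{start}, {end})")
            if start < prev_end:
                raise ValueError(f"overlapping compression period at {start}")
            if not (0 < depth < 10):
                raise ValueError(f"implausible depth {depth} cm")
            if not (0 < rate < 200):
                raise ValueError(f"implausible rate {rate} /min")
            prev_end = end


@dataclass(frozen=True)
class Violation:
    """One broken log invariant, naming the rule and offending timestamp."""

    rule: str
    timestamp: Optional[float]
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] {self.message}"


class LogParseError(ValueError):
    """Malformed event-log file; the message names the offending line."""


class LogValidationError(ValueError):
    """A syntactically readable log that breaks an invariant."""

    def __init__(self, violations: Sequence[Violation]):
        self.violations = list(violations)
        super().__init__("; ".join(str(v) for v in violations))


# Point events with clinical meaning: arrival must precede all of them.
_CLINICAL_KINDS = frozenset(EventKind) - {EventKind.ROSC}


def validate_log(log: EventLog) -> list[Violation]:
    """Check every log invariant; returns an empty list iff the log is valid.

    Never raises on a structurally readable log — validation is a reporting
    operation, so a file with several problems lists all of them.
    """
    out: list[Violation] = []
    if log.scenario_end <= log.arrival_time:
        out.append(
            Violation(
                "bounds",
                log.scenario_end,
                f"scenario_end {log.scenario_end} not after arrival {log.arrival_time}",
            )
        )
    ts = [e.timestamp for e in log.events]
    if any(b < a for a, b in zip(ts, ts[1:])):
        bad = next(b for a, b in zip(ts, ts[1:]) if b < a)
        out.append(Violation("order", bad, f"events not sorted at t={bad}"))
    for e in log.events:
        if not (0 <= e.timestamp <= log.scenario_end):
            out.append(
                Violation(
                    "bounds",
                    e.timestamp,
                    f"{e.kind.value} at t={e.timestamp} outside [0, {log.scenario_end}]",
                )
            )
    clinical = [e for e in log.events if e.kind in _CLINICAL_KINDS]
    if clinical and clinical[0].timestamp < log.arrival_time:
        e = clinical[0]
        out.append(
            Violation(
                "arrival",
                e.timestamp,
                f"{e.kind.value} at t={e.timestamp} precedes arrival at {log.arrival_time}",
            )
        )
    # Compression segments must strictly alternate start/stop, starting with a start.
    expect_start = True
    for e in log.events:
        if e.kind == EventKind.COMPRESSIONS_START:
            if not expect_start:
                out.append(
                    Violation("alternation", e.timestamp, f"two COMPRESSIONS_START in a row at t={e.timestamp}")
                )
            expect_start = False
        elif e.kind == EventKind.COMPRESSIONS_STOP:
            if expect_start:
                out.append(
                    Violation("alternation", e.timestamp, f"COMPRESSIONS_STOP without start at t={e.timestamp}")
                )
            expect_start = True
    # Rhythm checks are intervals: every END pairs with a preceding START.
    open_check = False
    for e in log.events:
        if e.kind == EventKind.RHYTHM_CHECK_START:
            if open_check:
                out.append(
                    Violation("pairing", e.timestamp, f"nested RHYTHM_CHECK_START at t={e.timestamp}")
                )
            open_check = True
        elif e.kind == EventKind.RHYTHM_CHECK_END:
            if not open_check:
                out.append(
                    Violation("pairing", e.timestamp, f"RHYTHM_CHECK_END without start at t={e.timestamp}")
                )
            open_check = False
    if log.rosc_time is not None and not (0 <= log.rosc_time <= log.scenario_end):
        out.append(Violation("bounds", log.rosc_time, f"rosc_time {log.rosc_time} outside scenario"))
    return out


_NULL = "NA"


def _fmt_opt(x: Optional[float]) -> str:
    return _NULL if x is None else repr(float(x))


def write_event_log(log: EventLog, path: str | Path) -> None:
    """Serialize a log to its self-contained delimited dialect.

    Optional fields are written as an explicit ``NA`` marker so that a read
    back reproduces the log field-for-field.
    """
    path = Path(path)
    lines = [
        f"# team_id={log.team_id}",
        f"# group={log.group.value}",
        f"# arrival_time_s={log.arrival_time!r}",
        f"# scenario_end_s={log.scenario_end!r}",
        f"# rosc_time_s={_fmt_opt(log.rosc_time)}",
        f"# excluded={'true' if log.excluded else 'false'}",
        f"# exclusion_reason={log.exclusion_reason}",
        "kind,timestamp_s",
    ]
    lines += [f"{e.kind.value},{e.timestamp!r}" for e in log.events]
    path.write_text("\n".join(lines) + "\n")


def read_event_log(path: str | Path, dialect: str = "csv") -> EventLog:
    """Parse and validate an event-log file.

    Raises :class:`LogParseError` naming the offending line on malformed input
    and :class:`LogValidationError` naming the broken rule on invariant
    violations.
    """
    if dialect != "csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    header: dict[str, str] = {}
    events: list[Event] = []
    saw_columns = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition("=")
            header[key.strip()] = value.strip()
            continue
        if not saw_columns:
            if line.replace(" ", "") != "kind,timestamp_s":
                raise LogParseError(f"{path}:{lineno}: expected column header 'kind,timestamp_s'")
            saw_columns = True
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise LogParseError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
        kind_s, ts_s = parts
        try:
            kind = EventKind(kind_s.strip())
        except ValueError as exc:
            raise LogParseError(f"{path}:{lineno}: unknown event kind {kind_s!r}") from exc
        try:
            ts = float(ts_s)
        except ValueError as exc:
            raise LogParseError(f"{path}:{lineno}: bad timestamp {ts_s!r}") from exc
        if ts < 0:
            raise LogParseError(f"{path}:{lineno}: negative timestamp {ts}")
        events.append(Event(kind, ts))
    try:
        rosc_s = header.get("rosc_time_s", _NULL)
        log = EventLog(
            team_id=header["team_id"],
            group=Group(header["group"]),
            arrival_time=float(header["arrival_time_s"]),
            scenario_end=float(header["scenario_end_s"]),
            events=tuple(events),
            excluded=header.get("excluded", "false").lower() == "true",
            exclusion_reason=header.get("exclusion_reason", ""),
            rosc_time=None if rosc_s == _NULL else float(rosc_s),
        )
    except (KeyError, ValueError) as exc:
        raise LogParseError(f"{path}: bad or missing header field: {exc}") from exc
    violations = validate_log(log)
    if violations:
        raise LogValidationError(violations)
    return log


def write_compression_series(series: CompressionSeries, path: str | Path) -> None:
    df = pd.DataFrame(
        list(series.samples),
        columns=["period_start_s", "period_end_s", "mean_depth_cm", "mean_rate_per_min"],
    )
    df.to_csv(path, index=False)


def read_compression_series(path: str | Path, team_id: str = "") -> CompressionSeries:
    df = pd.read_csv(path)
    required = ["period_start_s", "period_end_s", "mean_depth_cm", "mean_rate_per_min"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LogParseError(f"{path}: missing columns {missing}")
    samples = tuple(
        (float(r.period_start_s), float(r.period_end_s), float(r.mean_depth_cm), float(r.mean_rate_per_min))
        for r in df.itertuples()
    )
    return CompressionSeries(team_id=team_id, samples=samples, available=True)


MANIFEST_COLUMNS = [
    "team_id",
    "group",
    "arrival_time_s",
    "scenario_end_s",
    "event_file",
    "compression_file",
    "excluded",
    "exclusion_reason",
]


def write_manifest(rows: Iterable[dict], path: str | Path) -> None:
    df = pd.DataFrame(list(rows))
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    df[MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"team_id": str}, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise LogParseError(f"{path}: manifest missing columns {missing}")
    df["excluded"] = df["excluded"].astype(str).str.lower().isin(["true", "1", "yes"])
    return df


def load_cohort(
    manifest_path: str | Path,
) -> list[tuple[EventLog, Optional[CompressionSeries]]]:
    """Read every team referenced by a manifest (excluded teams included).

    Paths in the manifest are resolved relative to the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    out: list[tuple[EventLog, Optional[CompressionSeries]]] = []
    for row in read_manifest(manifest_path).itertuples():
        log = read_event_log(base / row.event_file)
        series: Optional[CompressionSeries] = None
        if str(row.compression_file).strip():
            series = read_compression_series(base / row.compression_file, team_id=log.team_id)
        out.append((log, series))
    return out
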