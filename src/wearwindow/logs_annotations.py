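"""Participant wear logs and manual window annotations.

Study protocols often pair the accelerometer with a paper log in which the
participant records the dates the device was first put on, worn, and removed.
This module parses such logs from a minimal CSV schema and converts each
record into a :class:`~wearwindow.wear_window.WearWindow` (method ``"log"``)
so it can be compared against the algorithm's window.

Log CSV schema (a deliberately minimal stand-in for study-specific paper
logs, which typically carry extra fields such as sleep times)::

    participant_id,date_on,date_off[,worn_1,...,worn_k]
    P001,2012-03-02,2012-03-08
    P002,2012-03-02,2012-03-08,1,1,1,0,1,1,1

``worn_i`` flags, when present, mark whether the device was actually worn on
each date from ``date_on`` to ``date_off`` inclusive (accepted spellings:
1/0, true/false, t/f, yes/no, y/n).  Malformed records are collected as
errors, not fatal — a large mailed-in study always has a few.

Manual annotations (e.g. from visual inspection of the signal) use the same
window JSON as the algorithm output, with method ``"manual"``; see
:func:`wearwindow.wear_window.read_window_json`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import date, timedelta

from .epoch_io import EpochSeries
from .wear_window import AlgorithmConfig, WearWindow

__all__ = ["LogRecord", "ParsedLogs", "parse_log", "log_to_window"]

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n"}


@dataclass(frozen=True)
class LogRecord:
    """One participant's log: on/off dates plus optional per-day worn flags."""

    participant_id: str
    date_on: date
    date_off: date
    worn_flags: tuple[bool, ...] | None = None

    def __post_init__(self) -> None:
        if self.date_on > self.date_off:
            raise ValueError(
                f"{self.participant_id}: date_on {self.date_on} after "
                f"date_off {self.date_off}"
            )
        if self.worn_flags is not None:
            span = (self.date_off - self.date_on).days + 1
            if len(self.worn_flags) != span:
                raise ValueError(
                    f"{self.participant_id}: {len(self.worn_flags)} worn flags "
                    f"for a {span}-date span"
                )

    @property
    def n_dates(self) -> int:
        return (self.date_off - self.date_on).days + 1


@dataclass(frozen=True)
class ParsedLogs:
    """Valid records plus per-record validation errors (row number, message)."""

    records: tuple[LogRecord, ...]
    errors: tuple[tuple[int, str], ...]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _parse_flag(text: str) -> bool:
    t = text.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise ValueError(f"unreadable worn flag {text!r}")


def parse_log(path) -> ParsedLogs:
    """Parse a log CSV; invalid records are collected, never fatal.

    A header row (first field ``participant_id``) is skipped if present.
    """
    records: list[LogRecord] = []
    errors: list[tuple[int, str]] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for rowno, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not f.strip() for f in row):
                continue
            if rowno == 1 and row[0].strip().lower() == "participant_id":
                continue
            try:
                if len(row) < 3:
                    raise ValueError("need at least participant_id,date_on,date_off")
                pid = row[0].strip()
                d_on = date.fromisoformat(row[1].strip())
                d_off = date.fromisoformat(row[2].strip())
                flags = None
                if len(row) > 3:
                    flags = tuple(_parse_flag(f) for f in row[3:] if f.strip() != "")
                    if not flags:
                        flags = None
                records.append(LogRecord(pid, d_on, d_off, flags))
            except ValueError as exc:
                errors.append((rowno, str(exc)))
    return ParsedLogs(tuple(records), tuple(errors))


def _longest_true_run(flags: tuple[bool, ...]) -> tuple[int, int] | None:
    """(start index, length) of the longest run of True; ties go earliest."""
    best: tuple[int, int] | None = None
    i = 0
    while i < len(flags):
        if flags[i]:
            j = i
            while j < len(flags) and flags[j]:
                j += 1
            if best is None or j - i > best[1]:
                best = (i, j - i)
            i = j
        else:
            i += 1
    return best


def log_to_window(
    record: LogRecord,
    max_window_days: int = 7,
    series: EpochSeries | None = None,
    config: AlgorithmConfig | None = None,
) -> WearWindow:
    """Derive the log's wear window (method ``"log"``).

    Without per-day flags the window is ``[date_on, date_off]`` capped at
    ``max_window_days`` from ``date_on``.  With flags it is the longest run
    of worn dates (earliest on ties), likewise capped.

    ``total_wear_hours`` stays ``None`` unless an :class:`EpochSeries` is
    supplied, in which case Choi wear hours over the window's dates are
    filled (the same non-wear stage the algorithm uses), so that
    hour-difference comparisons against the algorithm are meaningful.
    """
    if record.worn_flags is None:
        start = record.date_on
        n = min(record.n_dates, max_window_days)
        end = start + timedelta(days=n - 1)
    else:
        run = _longest_true_run(record.worn_flags)
        if run is None:
            return WearWindow.empty("log")
        i, length = run
        length = min(length, max_window_days)
        start = record.date_on + timedelta(days=i)
        end = start + timedelta(days=length - 1)

    hours: float | None = None
    if series is not None:
        from .wear_window import _choi_wear_minutes_for_run

        cfg = config or AlgorithmConfig()
        wm = _choi_wear_minutes_for_run(series, start, end, cfg)
        hours = sum(wm.values()) / 60.0
    return WearWindow.from_dates(start, end, hours, "log")
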