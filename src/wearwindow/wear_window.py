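"""Selection of a window of up to N consecutive days of 24-h accelerometer wear.

This is the OPACH wear-window algorithm: a screening rule for protocols that
ask participants to wear an actigraph around the clock for N (typically 7)
consecutive days, recorded over a slightly longer span of calendar days.  It
rests on a simple empirical signature — worn days show a substantial
proportion of non-zero count epochs, unworn days are almost entirely zeros
with a few solitary spikes — and proceeds in four steps:

1. Defining a day as midnight to 11:59 PM, keep the days whose fraction of
   non-zero epochs exceeds a threshold (default >10%).
2. If the first kept day opens with more than 8 h of consecutive zero counts
   from midnight, treat it as a partial-wear day and drop it (applied once).
3. If the surviving run of consecutive days is no longer than the window
   maximum (default 7), that run *is* the wear window — stop.
4. Otherwise run the Choi vector-magnitude non-wear classifier over the run
   and return the contiguous sub-window of maximum length with the most
   hours of classified wear.

All thresholds are strict inequalities.  An empty result (no day passes the
filter) is a value, not an error: signals with no apparent wear are reported
as an empty window and the caller decides what to do with them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta

from .epoch_io import (
    ConfigError,
    DayProfile,
    EpochSeries,
    partition_days,
    reepoch,
    slice_dates,
    vector_magnitude,
)
from .nonwear_choi import ChoiParams, classify_nonwear, wear_minutes_by_day

__all__ = [
    "AlgorithmConfig",
    "WearWindow",
    "candidate_days",
    "find_runs",
    "apply_first_day_rule",
    "select_wear_window",
    "detect_wear_window",
    "window_to_dict",
    "window_from_dict",
    "write_window_json",
    "read_window_json",
]


@dataclass(frozen=True)
class AlgorithmConfig:
    """Tuning parameters of the wear-window algorithm.

    Attributes
    ----------
    nonzero_fraction_threshold
        A day is a candidate wear day iff its fraction of non-zero epochs is
        strictly greater than this (default 0.10, i.e. ">10%").
    leading_zero_exclusion_hours
        The run's first day is dropped iff its run of zero-count epochs from
        midnight is strictly longer than this many hours (default 8).
    max_window_days
        Maximum window length in days (default 7).
    choi
        Parameters of the non-wear stage (only reached when the candidate run
        exceeds ``max_window_days``).
    nonzero_axis
        "vm" (default) or "vertical": how an epoch is judged non-zero.
    trailing_day_rule
        Off by default.  When on, the symmetric rule is also applied once to
        the run's last day (trailing zero run up to midnight > the exclusion
        hours drops it).
    """

    nonzero_fraction_threshold: float = 0.10
    leading_zero_exclusion_hours: float = 8.0
    max_window_days: int = 7
    choi: ChoiParams = field(default_factory=ChoiParams)
    nonzero_axis: str = "vm"
    trailing_day_rule: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.nonzero_fraction_threshold < 1.0):
            raise ConfigError("nonzero_fraction_threshold must lie in (0, 1)")
        if self.leading_zero_exclusion_hours <= 0:
            raise ConfigError("leading_zero_exclusion_hours must be positive")
        if self.max_window_days < 1:
            raise ConfigError("max_window_days must be >= 1")
        if self.nonzero_axis not in ("vm", "vertical"):
            raise ConfigError("nonzero_axis must be 'vm' or 'vertical'")


@dataclass(frozen=True)
class WearWindow:
    """A selected range of consecutive calendar dates of device wear.

    An empty window (``n_days == 0``) carries no dates.  ``total_wear_hours``
    is ``None`` when no epoch data were available to compute it (e.g. a
    log-derived window without an accompanying signal).
    """

    start_date: date | None
    end_date: date | None
    n_days: int
    total_wear_hours: float | None = None
    method: str = "algorithm"

    def __post_init__(self) -> None:
        if self.method not in ("algorithm", "log", "manual"):
            raise ConfigError(f"unknown method label {self.method!r}")
        if self.n_days < 0:
            raise ConfigError("n_days must be >= 0")
        if self.n_days == 0:
            if self.start_date is not None or self.end_date is not None:
                raise ConfigError("an empty window carries no dates")
        else:
            if self.start_date is None or self.end_date is None:
                raise ConfigError("a non-empty window needs both dates")
            if (self.end_date - self.start_date).days + 1 != self.n_days:
                raise ConfigError("n_days must equal end_date - start_date + 1")

    @classmethod
    def empty(cls, method: str = "algorithm") -> "WearWindow":
        return cls(None, None, 0, None, method)

    @classmethod
    def from_dates(
        cls,
        start: date,
        end: date,
        total_wear_hours: float | None = None,
        method: str = "algorithm",
    ) -> "WearWindow":
        return cls(start, end, (end - start).days + 1, total_wear_hours, method)

    @property
    def dates(self) -> list[date]:
        if self.n_days == 0:
            return []
        return [self.start_date + timedelta(days=i) for i in range(self.n_days)]


def candidate_days(
    profiles: list[DayProfile], config: AlgorithmConfig | None = None
) -> list[DayProfile]:
    """Days whose non-zero-epoch fraction strictly exceeds the threshold.

    A day at exactly the threshold (e.g. exactly 10%) is excluded.
    """
    config = config or AlgorithmConfig()
    thr = config.nonzero_fraction_threshold
    return [p for p in profiles if p.fraction_nonzero > thr]


def find_runs(days: list[DayProfile]) -> list[list[DayProfile]]:
    """Partition date-ordered days into maximal runs of consecutive dates."""
    runs: list[list[DayProfile]] = []
    for p in days:
        if runs and (p.date - runs[-1][-1].date).days == 1:
            runs[-1].append(p)
        else:
            if runs and (p.date - runs[-1][-1].date).days < 1:
                raise ConfigError(f"duplicate or out-of-order date {p.date}")
            runs.append([p])
    return runs


def _choose_run(runs: list[list[DayProfile]]) -> list[DayProfile]:
    """Longest run; ties broken by summed non-zero fraction, then earliest.

    Deterministic and biased toward the dominant cluster of wear days (in
    practice a 24-h protocol yields a single cluster).
    """
    return max(
        runs,
        key=lambda r: (len(r), sum(p.fraction_nonzero for p in r), -r[0].date.toordinal()),
    )


def apply_first_day_rule(
    run: list[DayProfile], config: AlgorithmConfig | None = None
) -> list[DayProfile]:
    """Drop the run's first day iff it opens with > the exclusion hours of zeros.

    Applied once, never iterated; a first day at exactly the limit (e.g.
    exactly 8 h) is retained.
    """
    config = config or AlgorithmConfig()
    if run and run[0].leading_zero_hours > config.leading_zero_exclusion_hours:
        return run[1:]
    return list(run)


def _choi_wear_minutes_for_run(
    series: EpochSeries, run_start: date, run_end: date, config: AlgorithmConfig
) -> dict[date, int]:
    """Choi wear minutes per date over the subseries spanning the run's days."""
    sub = slice_dates(series, run_start, run_end)
    if sub.epoch_length > 60:
        raise ConfigError(
            "the non-wear stage needs 60-s epochs; epoch lengths above 60 s "
            "cannot be re-epoched down"
        )
    sub60 = sub if sub.epoch_length == 60 else reepoch(sub, 60)
    mask = classify_nonwear(vector_magnitude(sub60), config.choi)
    return wear_minutes_by_day(mask, sub60)


def detect_wear_window(
    series: EpochSeries, config: AlgorithmConfig | None = None
) -> tuple[WearWindow, list[DayProfile]]:
    """Run the full algorithm; return the window plus per-day diagnostics.

    The returned profiles cover every recorded calendar day;
    ``choi_wear_minutes`` is filled for the days of the chosen run (the only
    days the non-wear stage ever sees).
    """
    config = config or AlgorithmConfig()
    profiles = partition_days(series, axis=config.nonzero_axis)
    cands = candidate_days(profiles, config)
    runs = find_runs(cands)
    if not runs:
        return WearWindow.empty(), profiles

    run = _choose_run(runs)
    run = apply_first_day_rule(run, config)
    if config.trailing_day_rule and run:
        trailing = _trailing_zero_hours(series, run[-1], config.nonzero_axis)
        if trailing > config.leading_zero_exclusion_hours:
            run = run[:-1]
    if not run:
        return WearWindow.empty(), profiles

    wear_min = _choi_wear_minutes_for_run(series, run[0].date, run[-1].date, config)
    for p in profiles:
        if p.date in wear_min:
            p.choi_wear_minutes = float(wear_min[p.date])

    if len(run) <= config.max_window_days:
        start, end = run[0].date, run[-1].date
    else:
        # guideline 4: best max_window_days-day sub-window by wear minutes,
        # ties going to the earliest start
        best_start, best_total = None, -1
        for i in range(len(run) - config.max_window_days + 1):
            days = run[i : i + config.max_window_days]
            total = sum(wear_min.get(p.date, 0) for p in days)
            if total > best_total:
                best_start, best_total = i, total
        start = run[best_start].date
        end = run[best_start + config.max_window_days - 1].date

    total_hours = sum(
        wear_min.get(start + timedelta(days=i), 0)
        for i in range((end - start).days + 1)
    ) / 60.0
    return WearWindow.from_dates(start, end, total_hours, "algorithm"), profiles


def _trailing_zero_hours(series: EpochSeries, day: DayProfile, axis: str) -> float:
    import numpy as np

    sub = slice_dates(series, day.date, day.date)
    if axis == "vm":
        nz = sub.counts.any(axis=1)
    else:
        nz = sub.counts[:, 0] > 0
    trail = int(np.argmax(nz[::-1])) if nz.any() else len(sub)
    return trail * sub.epoch_length / 3600.0


def select_wear_window(
    series: EpochSeries, config: AlgorithmConfig | None = None
) -> WearWindow:
    """The algorithm's wear window for a signal (see module docstring)."""
    return detect_wear_window(series, config)[0]


# ---------------------------------------------------------------------------
# Window JSON (shared by algorithm output and manual annotations)
# ---------------------------------------------------------------------------

def window_to_dict(window: WearWindow) -> dict:
    return {
        "start_date": window.start_date.isoformat() if window.start_date else None,
        "end_date": window.end_date.isoformat() if window.end_date else None,
        "n_days": window.n_days,
        "total_wear_hours": window.total_wear_hours,
        "method": window.method,
    }


def window_from_dict(d: dict) -> WearWindow:
    start = date.fromisoformat(d["start_date"]) if d.get("start_date") else None
    end = date.fromisoformat(d["end_date"]) if d.get("end_date") else None
    n = int(d.get("n_days", 0 if start is None else (end - start).days + 1))
    twh = d.get("total_wear_hours")
    return WearWindow(start, end, n, None if twh is None else float(twh),
                      d.get("method", "manual"))


def write_window_json(
    window: WearWindow,
    path,
    *,
    config: AlgorithmConfig | None = None,
    profiles: list[DayProfile] | None = None,
) -> None:
    """Write a window (plus optional config echo and per-day audit) as JSON."""
    payload = window_to_dict(window)
    if config is not None:
        payload["config"] = {
            "nonzero_fraction_threshold": config.nonzero_fraction_threshold,
            "leading_zero_exclusion_hours": config.leading_zero_exclusion_hours,
            "max_window_days": config.max_window_days,
            "nonzero_axis": config.nonzero_axis,
            "trailing_day_rule": config.trailing_day_rule,
            "choi": {
                "min_nonwear_minutes": config.choi.min_nonwear_minutes,
                "spike_tolerance_minutes": config.choi.spike_tolerance_minutes,
                "flank_window_minutes": config.choi.flank_window_minutes,
            },
        }
    if profiles is not None:
        payload["days"] = [
            {
                "date": p.date.isoformat(),
                "n_epochs": p.n_epochs,
                "fraction_nonzero": p.fraction_nonzero,
                "leading_zero_hours": p.leading_zero_hours,
                "choi_wear_minutes": p.choi_wear_minutes,
            }
            for p in profiles
        ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_window_json(path) -> WearWindow:
    with open(path, "r", encoding="utf-8") as fh:
        return window_from_dict(json.load(fh))
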