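"""Seeded simulator of multi-day accelerometer count signals with known truth.

The generator emulates the empirical structure of 24-h hip-worn actigraph
signals that the wear-window algorithm exploits:

* during wear, epochs show a substantial proportion of non-zero counts —
  modeled as a zero-inflated heavy-tailed count process (each wear epoch is
  zero with probability ``p_zero_during_wear``, otherwise its axis counts are
  drawn from a rounded lognormal);
* during non-wear, counts are zero except for rare solitary spikes —
  modeled as isolated single-epoch (width configurable) bursts at
  ``spike_rate_per_hour``.

The default protocol spans nine calendar days targeting seven full wear
days: the device goes on mid-morning of day 1, is worn continuously through
day 8, and comes off on the morning of day 9.  Optional within-day removal
episodes (e.g. bathing) carve non-wear blocks out of scheduled wear.

Every simulation is fully reproducible from ``spec.seed`` and returns the
planted ground-truth window, derived analytically from the wear schedule, so
detector recovery can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime, timedelta

import numpy as np

from .epoch_io import ConfigError, EpochSeries
from .logs_annotations import LogRecord
from .wear_window import WearWindow

__all__ = [
    "SimulationSpec",
    "SimulatedSignal",
    "simulate_signal",
    "simulate_log",
    "expected_nonzero_fraction",
    "planted_window",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated protocol run.

    ``wear_schedule`` is a per-day tuple of ``(start_hour, end_hour)`` wear
    intervals (clock hours in [0, 24], non-overlapping).  When ``None`` the
    default protocol is built from ``n_calendar_days``, ``first_day_on_hour``
    and ``last_day_off_hour``.  ``removal_episodes`` are
    ``(day_index, start_hour, end_hour)`` blocks subtracted from scheduled
    wear.  The ground-truth window is computed from the schedule with the
    stated filter parameters and capped at ``max_window_days``.
    """

    n_calendar_days: int = 9
    epoch_length: int = 15
    start_date: date = date(2012, 3, 1)
    wear_schedule: tuple | None = None
    first_day_on_hour: float = 10.0
    last_day_off_hour: float = 9.0
    p_zero_during_wear: float = 0.5
    magnitude_log_mean: float = 4.5
    magnitude_log_sigma: float = 1.0
    spike_rate_per_hour: float = 0.5
    spike_width_epochs: int = 1
    removal_episodes: tuple = ()
    seed: int = 0
    log_shift_probs: tuple = ((0, 1.0),)
    p_missing_log: float = 0.057
    max_window_days: int = 7
    nonzero_fraction_threshold: float = 0.10
    leading_zero_exclusion_hours: float = 8.0

    def __post_init__(self) -> None:
        if self.n_calendar_days < 1:
            raise ConfigError("n_calendar_days must be >= 1")
        if 86_400 % self.epoch_length != 0:
            raise ConfigError("epoch_length must divide 86400 s")
        if not (0.0 <= self.p_zero_during_wear <= 1.0):
            raise ConfigError("p_zero_during_wear must lie in [0, 1]")
        if self.spike_rate_per_hour < 0:
            raise ConfigError("spike_rate_per_hour must be >= 0")
        if self.spike_width_epochs < 1:
            raise ConfigError("spike_width_epochs must be >= 1")
        if not (0.0 <= self.p_missing_log <= 1.0):
            raise ConfigError("p_missing_log must lie in [0, 1]")
        total = sum(p for _, p in self.log_shift_probs)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigError("log_shift_probs must sum to 1")
        for day in self.resolved_schedule():
            last_end = 0.0
            for a, b in day:
                if not (0.0 <= a < b <= 24.0):
                    raise ConfigError(f"wear interval ({a}, {b}) outside the day")
                if a < last_end:
                    raise ConfigError("overlapping wear intervals")
                last_end = b
        for d, a, b in self.removal_episodes:
            if not (0 <= d < self.n_calendar_days) or not (0.0 <= a < b <= 24.0):
                raise ConfigError(f"infeasible removal episode ({d}, {a}, {b})")

    @property
    def epochs_per_day(self) -> int:
        return 86_400 // self.epoch_length

    def resolved_schedule(self) -> tuple:
        """The effective per-day wear schedule (defaults expanded, sorted)."""
        if self.wear_schedule is not None:
            if len(self.wear_schedule) != self.n_calendar_days:
                raise ConfigError("wear_schedule must list every calendar day")
            return tuple(
                tuple(sorted((float(a), float(b)) for a, b in day))
                for day in self.wear_schedule
            )
        if self.n_calendar_days == 1:
            return (((self.first_day_on_hour, self.last_day_off_hour),),)
        days = [((self.first_day_on_hour, 24.0),)]
        days += [((0.0, 24.0),)] * (self.n_calendar_days - 2)
        days += [((0.0, self.last_day_off_hour),)]
        return tuple(days)

    @property
    def spike_prob_per_epoch(self) -> float:
        return min(1.0, self.spike_rate_per_hour * self.epoch_length / 3600.0)


@dataclass(frozen=True)
class SimulatedSignal:
    """A simulated series plus its planted truth."""

    series: EpochSeries
    truth: WearWindow
    wear_mask: np.ndarray  # per-epoch scheduled-wear indicator


def _scheduled_wear_mask(spec: SimulationSpec) -> np.ndarray:
    """Per-epoch boolean: is this epoch inside scheduled wear (minus removals)?"""
    epd = spec.epochs_per_day
    mask = np.zeros(spec.n_calendar_days * epd, dtype=bool)
    for d, day in enumerate(spec.resolved_schedule()):
        for a, b in day:
            i0 = d * epd + round(a * 3600 / spec.epoch_length)
            i1 = d * epd + round(b * 3600 / spec.epoch_length)
            mask[i0:i1] = True
    for d, a, b in spec.removal_episodes:
        i0 = d * epd + round(a * 3600 / spec.epoch_length)
        i1 = d * epd + round(b * 3600 / spec.epoch_length)
        mask[i0:i1] = False
    return mask


def expected_nonzero_fraction(spec: SimulationSpec, day: int) -> float:
    """Analytic expectation of a day's non-zero-epoch fraction.

    Exact for single-epoch spikes (each non-wear epoch hosts a spike
    independently with probability ``rate * epoch_length / 3600``); for wider
    spikes the non-wear term uses the first-order approximation
    ``rate * width * epoch_length / 3600``.
    """
    epd = spec.epochs_per_day
    wear = _scheduled_wear_mask(spec)[day * epd : (day + 1) * epd]
    n_wear = int(np.count_nonzero(wear))
    p_spike = min(1.0, spec.spike_prob_per_epoch * spec.spike_width_epochs)
    return (
        n_wear * (1.0 - spec.p_zero_during_wear) + (epd - n_wear) * p_spike
    ) / epd


def planted_window(spec: SimulationSpec) -> WearWindow:
    """Ground-truth window implied by the schedule (no sampling noise).

    Mirrors the detection pipeline on the *scheduled* signal: days whose
    expected non-zero fraction exceeds the threshold, the longest run
    (ties: highest summed fraction, then earliest), the first-day rule on
    scheduled leading zeros, and — if the run is longer than
    ``max_window_days`` — the sub-window with the most scheduled wear hours
    (earliest on ties).  ``total_wear_hours`` is the scheduled wear within
    the window.
    """
    epd = spec.epochs_per_day
    wear = _scheduled_wear_mask(spec)
    fracs = [expected_nonzero_fraction(spec, d) for d in range(spec.n_calendar_days)]
    cands = [d for d in range(spec.n_calendar_days)
             if fracs[d] > spec.nonzero_fraction_threshold]
    if not cands:
        return WearWindow.empty("manual")

    runs: list[list[int]] = [[cands[0]]]
    for d in cands[1:]:
        if d == runs[-1][-1] + 1:
            runs[-1].append(d)
        else:
            runs.append([d])
    run = max(runs, key=lambda r: (len(r), sum(fracs[d] for d in r), -r[0]))

    day0 = wear[run[0] * epd : (run[0] + 1) * epd]
    lead_h = (int(np.argmax(day0)) if day0.any() else epd) * spec.epoch_length / 3600.0
    if lead_h > spec.leading_zero_exclusion_hours:
        run = run[1:]
    if not run:
        return WearWindow.empty("manual")

    day_wear_epochs = [
        int(np.count_nonzero(wear[d * epd : (d + 1) * epd])) for d in run
    ]
    if len(run) <= spec.max_window_days:
        i0, n = 0, len(run)
    else:
        n = spec.max_window_days
        totals = [sum(day_wear_epochs[i : i + n]) for i in range(len(run) - n + 1)]
        i0 = int(np.argmax(totals))  # argmax takes the earliest on ties
    start = spec.start_date + timedelta(days=run[i0])
    end = spec.start_date + timedelta(days=run[i0 + n - 1])
    hours = sum(day_wear_epochs[i0 : i0 + n]) * spec.epoch_length / 3600.0
    return WearWindow.from_dates(start, end, hours, "manual")


def simulate_signal(spec: SimulationSpec | None = None) -> SimulatedSignal:
    """Draw one signal from the spec; bit-reproducible from ``spec.seed``."""
    spec = spec or SimulationSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_calendar_days * spec.epochs_per_day
    wear = _scheduled_wear_mask(spec)

    active = wear & (rng.random(n) >= spec.p_zero_during_wear)
    spikes = (~wear) & (rng.random(n) < spec.spike_prob_per_epoch)
    if spec.spike_width_epochs > 1:
        widened = spikes.copy()
        for w in range(1, spec.spike_width_epochs):
            widened[w:] |= spikes[:-w]
        spikes = widened & ~wear
    nonzero = active | spikes

    counts = np.zeros((n, 3), dtype=np.int64)
    k = int(np.count_nonzero(nonzero))
    if k:
        mu, sg = spec.magnitude_log_mean, spec.magnitude_log_sigma
        x = np.maximum(1, np.rint(rng.lognormal(mu, sg, k))).astype(np.int64)
        y = np.rint(rng.lognormal(mu - 0.7, sg, k)).astype(np.int64)
        z = np.rint(rng.lognormal(mu - 1.0, sg, k)).astype(np.int64)
        counts[nonzero, 0] = x
        counts[nonzero, 1] = y
        counts[nonzero, 2] = z

    series = EpochSeries(
        datetime.combine(spec.start_date, datetime.min.time()),
        spec.epoch_length,
        counts,
        device_id=f"sim{spec.seed}",
    )
    return SimulatedSignal(series, planted_window(spec), wear)


def simulate_log(
    truth: WearWindow,
    spec: SimulationSpec,
    participant_id: str = "SIM",
    seed: int | None = None,
) -> LogRecord | None:
    """A (possibly missing, possibly shifted) participant log for a truth window.

    With probability ``spec.p_missing_log`` no log is returned — mirroring
    real cohorts where a few percent of mailed-in logs never arrive.
    Otherwise the truth dates are shifted by a draw from
    ``spec.log_shift_probs``.  An empty truth window yields no log.
    """
    if truth.n_days == 0:
        return None
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    if rng.random() < spec.p_missing_log:
        return None
    shifts = [s for s, _ in spec.log_shift_probs]
    probs = [p for _, p in spec.log_shift_probs]
    shift = int(rng.choice(shifts, p=probs))
    return LogRecord(
        participant_id,
        truth.start_date + timedelta(days=shift),
        truth.end_date + timedelta(days=shift),
    )
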