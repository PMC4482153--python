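"""Choi vector-magnitude non-wear classification on one-minute epochs.

The classifier labels each minute as wear or non-wear from the per-minute
vector-magnitude count series.  A minute is non-wear iff it lies in an
interval of at least ``min_nonwear_minutes`` consecutive zero-VM minutes,
where short interruptions — at most ``spike_tolerance_minutes`` consecutive
non-zero minutes — are absorbed into the interval as artifact, provided the
``flank_window_minutes`` minutes on each side of the interruption contain no
other non-zero minute.  These "solitary spikes" inside long zero runs are a
characteristic signature of an unworn device sitting on a table.

Defaults (90 / 2 / 30 min) follow the vector-magnitude variant of the Choi
algorithm; all three are tunable for other protocols.  Counts are first
aggregated to 60-s epochs by per-axis summation (see
:func:`wearwindow.epoch_io.reepoch`) and VM is taken of the summed axes,
matching the count-aggregation convention of device epoch exports.

Boundary behavior: an interruption whose flank window is truncated by the
series edge is judged on the available minutes only (no padding), and an
all-zero series shorter than ``min_nonwear_minutes`` is classified all-wear
— the interval rule applied literally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np

from .epoch_io import ConfigError, EpochFormatError, EpochSeries

__all__ = ["ChoiParams", "NonWearMask", "classify_nonwear", "wear_minutes_by_day",
           "write_mask_csv"]


@dataclass(frozen=True)
class ChoiParams:
    """Tuning parameters of the non-wear classifier, all in minutes."""

    min_nonwear_minutes: int = 90
    spike_tolerance_minutes: int = 2
    flank_window_minutes: int = 30

    def __post_init__(self) -> None:
        if self.min_nonwear_minutes < 1:
            raise ConfigError("min_nonwear_minutes must be >= 1")
        if self.spike_tolerance_minutes < 0:
            raise ConfigError("spike_tolerance_minutes must be >= 0")
        if self.flank_window_minutes < 0:
            raise ConfigError("flank_window_minutes must be >= 0")


@dataclass(frozen=True)
class NonWearMask:
    """Per-minute wear classification aligned to a 60-s epoch series.

    ``wear[i]`` is True when minute ``i`` is classified as worn.  By
    construction every maximal run of non-wear minutes lasts at least
    ``params.min_nonwear_minutes``.
    """

    wear: np.ndarray
    params: ChoiParams = field(default_factory=ChoiParams)

    def __post_init__(self) -> None:
        object.__setattr__(self, "wear", np.asarray(self.wear, dtype=bool))

    def __len__(self) -> int:
        return self.wear.size

    @property
    def nonwear_minutes(self) -> int:
        return int(np.count_nonzero(~self.wear))

    @property
    def wear_minutes(self) -> int:
        return int(np.count_nonzero(self.wear))


def _true_runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start (inclusive) and end (exclusive) indices of maximal True runs."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    d = np.diff(m.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.concatenate(([0], starts))
    if m[-1]:
        ends = np.concatenate((ends, [m.size]))
    return starts.astype(np.int64), ends.astype(np.int64)


def classify_nonwear(vm60, params: ChoiParams | None = None) -> NonWearMask:
    """Classify each minute of a per-minute VM series as wear or non-wear.

    Parameters
    ----------
    vm60
        Non-negative per-minute vector-magnitude counts (one value per 60-s
        epoch), e.g. ``vector_magnitude(reepoch(series, 60))``.
    params
        Classifier tuning; defaults to :class:`ChoiParams`.

    Returns a :class:`NonWearMask` (True = wear).  The function is pure:
    identical inputs always give identical masks.
    """
    params = params or ChoiParams()
    vm = np.asarray(vm60, dtype=np.float64)
    if vm.ndim != 1 or vm.size == 0:
        raise EpochFormatError("vm60 must be a non-empty 1-D series")
    if np.any(vm < 0):
        raise EpochFormatError("vector magnitudes must be non-negative")

    n = vm.size
    nonzero = vm > 0
    # prefix sums of the non-zero indicator, for O(1) flank-window checks
    csum = np.concatenate(([0], np.cumsum(nonzero, dtype=np.int64)))

    absorbed = np.zeros(n, dtype=bool)
    run_starts, run_ends = _true_runs(nonzero)
    tol = params.spike_tolerance_minutes
    flank = params.flank_window_minutes
    for s, e in zip(run_starts, run_ends):
        if e - s > tol:
            continue
        lo = max(0, s - flank)
        hi = min(n, e + flank)
        # flanks (truncated at the edges) must contain no other non-zero minute
        if csum[s] - csum[lo] == 0 and csum[hi] - csum[e] == 0:
            absorbed[s:e] = True

    effectively_zero = ~nonzero | absorbed
    wear = np.ones(n, dtype=bool)
    z_starts, z_ends = _true_runs(effectively_zero)
    long_enough = (z_ends - z_starts) >= params.min_nonwear_minutes
    for s, e in zip(z_starts[long_enough], z_ends[long_enough]):
        wear[s:e] = False
    return NonWearMask(wear, params)


def wear_minutes_by_day(mask: NonWearMask, series60: EpochSeries) -> dict[date, int]:
    """Wear-classified minutes per calendar date.

    ``series60`` must be the 60-s epoch series the mask was computed from;
    a length mismatch raises :class:`~wearwindow.epoch_io.ConfigError`.
    """
    if series60.epoch_length != 60:
        raise ConfigError("wear_minutes_by_day requires a 60-s epoch series")
    if len(mask) != len(series60):
        raise ConfigError(
            f"mask length {len(mask)} does not match series length {len(series60)}"
        )
    from datetime import timedelta

    day_idx = series60.epoch_dates()
    first = series60.start_time.date()
    totals = np.bincount(day_idx, weights=mask.wear.astype(np.float64))
    out: dict[date, int] = {}
    for d in np.unique(day_idx):
        out[first + timedelta(days=int(d))] = int(totals[d])
    return out


def write_mask_csv(mask: NonWearMask, series60: EpochSeries, path) -> None:
    """Audit export: one ``timestamp,wear`` row per minute (wear in {0,1})."""
    if len(mask) != len(series60):
        raise ConfigError("mask/series length mismatch")
    stamps = series60.timestamps().strftime("%Y-%m-%dT%H:%M:%S")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("timestamp,wear\n")
        for t, w in zip(stamps, mask.wear):
            fh.write(f"{t},{int(w)}\n")
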