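"""Slow, literal reference implementations used for validation.

These re-state the non-wear interval rule and the window-selection pipeline
in the most direct form possible — plain-Python scans and exhaustive
enumeration of candidate day ranges and sub-windows — so the optimized
implementations can be checked against them on randomized inputs.  They are
deliberately independent of the vectorized code paths and are never used in
production.
"""

from __future__ import annotations

import math
from datetime import date, datetime, timedelta

from .epoch_io import EpochSeries
from .nonwear_choi import ChoiParams
from .wear_window import AlgorithmConfig, WearWindow

__all__ = ["classify_nonwear_reference", "select_wear_window_bruteforce"]

SECONDS_PER_DAY = 86_400


def classify_nonwear_reference(vm60, params: ChoiParams | None = None) -> list[bool]:
    """Literal per-minute scan of the non-wear interval rule (True = wear).

    Enumerates every maximal non-zero run; runs no longer than the spike
    tolerance whose flank windows (truncated at the series edges) are all
    zero are absorbed; then every maximal run of effectively-zero minutes at
    least the minimum non-wear length becomes non-wear.
    """
    params = params or ChoiParams()
    vm = [float(v) for v in vm60]
    if any(v < 0 for v in vm):
        raise ValueError("vector magnitudes must be non-negative")
    n = len(vm)
    nonzero = [v > 0 for v in vm]

    absorbed = [False] * n
    i = 0
    while i < n:
        if nonzero[i]:
            j = i
            while j < n and nonzero[j]:
                j += 1
            if j - i <= params.spike_tolerance_minutes:
                left = all(
                    not nonzero[k]
                    for k in range(max(0, i - params.flank_window_minutes), i)
                )
                right = all(
                    not nonzero[k]
                    for k in range(j, min(n, j + params.flank_window_minutes))
                )
                if left and right:
                    for k in range(i, j):
                        absorbed[k] = True
            i = j
        else:
            i += 1

    eff_zero = [(not nonzero[k]) or absorbed[k] for k in range(n)]
    wear = [True] * n
    i = 0
    while i < n:
        if eff_zero[i]:
            j = i
            while j < n and eff_zero[j]:
                j += 1
            if j - i >= params.min_nonwear_minutes:
                for k in range(i, j):
                    wear[k] = False
            i = j
        else:
            i += 1
    return wear


def _vm(x: int, y: int, z: int) -> float:
    return math.sqrt(x * x + y * y + z * z)


def select_wear_window_bruteforce(
    series: EpochSeries, config: AlgorithmConfig | None = None
) -> WearWindow:
    """Exhaustive-enumeration counterpart of ``select_wear_window``.

    Recomputes day summaries epoch by epoch, finds maximal candidate runs by
    testing *every* contiguous date range for membership and maximality,
    applies the first-day rule, and — when the run exceeds the window
    maximum — scores every sub-window with wear minutes from the literal
    non-wear reference above.
    """
    config = config or AlgorithmConfig()
    eplen = series.epoch_length
    counts = series.counts
    n = len(series)
    midnight = datetime.combine(series.start_time.date(), datetime.min.time())
    offset = int((series.start_time - midnight).total_seconds())

    # per-day tallies, one epoch at a time
    per_day: dict[int, dict] = {}
    for i in range(n):
        d = (offset + i * eplen) // SECONDS_PER_DAY
        if config.nonzero_axis == "vm":
            nz = bool(counts[i, 0] or counts[i, 1] or counts[i, 2])
        else:
            nz = bool(counts[i, 0])
        rec = per_day.setdefault(
            d, {"n": 0, "nz": 0, "lead": 0, "in_lead": True, "first": i}
        )
        rec["n"] += 1
        if nz:
            rec["nz"] += 1
            rec["in_lead"] = False
        elif rec["in_lead"]:
            rec["lead"] += 1

    days = sorted(per_day)
    fracs = {d: per_day[d]["nz"] / per_day[d]["n"] for d in days}
    cands = {d for d in days if fracs[d] > config.nonzero_fraction_threshold}
    if not cands:
        return WearWindow.empty()

    # every contiguous date range that is entirely candidate and maximal
    runs: list[list[int]] = []
    for a in days:
        for b in days:
            if b < a:
                continue
            rng = list(range(a, b + 1))
            if all(d in cands for d in rng) and (a - 1) not in cands and (b + 1) not in cands:
                runs.append(rng)
    run = max(
        runs, key=lambda r: (len(r), sum(fracs[d] for d in r), -r[0])
    )

    lead_h = per_day[run[0]]["lead"] * eplen / 3600.0
    if lead_h > config.leading_zero_exclusion_hours:
        run = run[1:]
    if not run:
        return WearWindow.empty()

    # literal non-wear stage over the epochs of the run's calendar days
    lo = per_day[run[0]]["first"]
    hi = per_day[run[-1]]["first"] + per_day[run[-1]]["n"]
    k = 60 // eplen
    vm60: list[float] = []
    minute_day: list[int] = []
    run_offset = offset + lo * eplen
    for m in range((hi - lo) // k):
        sx = sy = sz = 0
        for i in range(lo + m * k, lo + (m + 1) * k):
            sx += int(counts[i, 0])
            sy += int(counts[i, 1])
            sz += int(counts[i, 2])
        vm60.append(_vm(sx, sy, sz))
        minute_day.append((run_offset + m * 60) // SECONDS_PER_DAY)
    wear = classify_nonwear_reference(vm60, config.choi)
    wear_min: dict[int, int] = {d: 0 for d in run}
    for m, w in enumerate(wear):
        if w and minute_day[m] in wear_min:
            wear_min[minute_day[m]] += 1

    if len(run) <= config.max_window_days:
        chosen = run
    else:
        best, best_total = None, -1
        for i in range(len(run) - config.max_window_days + 1):
            sub = run[i : i + config.max_window_days]
            total = sum(wear_min[d] for d in sub)
            if total > best_total:
                best, best_total = sub, total
        chosen = best

    first_date = series.start_time.date()
    start = first_date + timedelta(days=chosen[0])
    end = first_date + timedelta(days=chosen[-1])
    hours = sum(wear_min[d] for d in chosen) / 60.0
    return WearWindow.from_dates(start, end, hours, "algorithm")
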