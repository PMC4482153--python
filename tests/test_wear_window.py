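"""Wear-window selection: day filter, runs, first-day rule, full pipeline."""

from dataclasses import replace
from datetime import date, datetime, timedelta

import numpy as np
import pytest

from wearwindow import (
    AlgorithmConfig,
    ChoiParams,
    ConfigError,
    DayProfile,
    EpochSeries,
    WearWindow,
    apply_first_day_rule,
    candidate_days,
    detect_wear_window,
    find_runs,
    select_wear_window,
    window_from_dict,
    window_to_dict,
)
from wearwindow.reference import select_wear_window_bruteforce
from wearwindow.synthetic import SimulationSpec, simulate_signal

from conftest import EPD_15, day_epochs, series_from_days

D0 = date(2012, 3, 1)


def profile(day_offset: int, frac: float, lead_h: float = 0.0) -> DayProfile:
    return DayProfile(
        date=D0 + timedelta(days=day_offset),
        first_epoch_index=day_offset * EPD_15,
        n_epochs=EPD_15,
        fraction_nonzero=frac,
        leading_zero_hours=lead_h,
    )


class TestCandidateDays:
    def test_exactly_ten_percent_is_excluded(self):
        # 576/5760 = 0.10 exactly: the ">" is strict
        profs = [profile(0, 576 / 5760), profile(1, 0.5)]
        kept = candidate_days(profs)
        assert [p.date for p in kept] == [D0 + timedelta(days=1)]

    def test_just_above_threshold_included(self):
        profs = [profile(0, 600 / 5760)]  # 0.1041... > 0.10
        assert candidate_days(profs) == profs

    def test_all_zero_signal_yields_no_candidates(self):
        assert candidate_days([profile(i, 0.0) for i in range(9)]) == []

    def test_threshold_monotonicity(self):
        profs = [profile(i, f) for i, f in enumerate((0.05, 0.12, 0.3, 0.08, 0.5))]
        n_prev = None
        for thr in (0.05, 0.10, 0.20, 0.40):
            n = len(candidate_days(profs, AlgorithmConfig(nonzero_fraction_threshold=thr)))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n


class TestFindRuns:
    def test_single_block(self):
        profs = [profile(i, 0.5) for i in range(2, 9)]
        runs = find_runs(profs)
        assert len(runs) == 1 and len(runs[0]) == 7

    def test_two_runs(self):
        profs = [profile(i, 0.5) for i in (1, 2, 4, 5, 6)]
        runs = find_runs(profs)
        assert [len(r) for r in runs] == [2, 3]

    def test_empty_input(self):
        assert find_runs([]) == []

    def test_duplicate_dates_rejected(self):
        with pytest.raises(ConfigError):
            find_runs([profile(1, 0.5), profile(1, 0.6)])


class TestFirstDayRule:
    def test_8_25_hours_removed(self):
        run = [profile(0, 0.5, lead_h=1980 * 15 / 3600), profile(1, 0.5)]
        out = apply_first_day_rule(run)
        assert [p.date for p in out] == [D0 + timedelta(days=1)]

    def test_exactly_8_hours_retained(self):
        run = [profile(0, 0.5, lead_h=8.0), profile(1, 0.5)]
        assert apply_first_day_rule(run) == run

    def test_applied_once_not_iterated(self):
        run = [profile(0, 0.5, lead_h=9.0), profile(1, 0.5, lead_h=10.0)]
        out = apply_first_day_rule(run)
        assert len(out) == 1  # second day kept despite its own long lead

    def test_single_day_run_can_empty(self):
        assert apply_first_day_rule([profile(0, 0.5, lead_h=9.0)]) == []


def _alternating_day(lead_zero: int = 0) -> np.ndarray:
    """Full wear day: non-zero on every other 15-s epoch (fraction ~0.5)."""
    n = (EPD_15 - lead_zero) // 2
    return day_epochs(n, lead_zero=lead_zero, alternate=True)


def _sparse_day(n_nonzero: int = 100) -> np.ndarray:
    """Non-wear-like day: a few scattered solitary spikes (fraction < 0.05)."""
    return day_epochs(n_nonzero)


def _day_with_zero_block(start_min: int, n_min: int) -> np.ndarray:
    day = _alternating_day()
    day[start_min * 4 : (start_min + n_min) * 4] = 0
    return day


class TestSelectWearWindow:
    def test_all_zero_signal_gives_empty_window(self):
        s = series_from_days([day_epochs(0) for _ in range(9)])
        w = select_wear_window(s)
        assert w.n_days == 0 and w.start_date is None

    def test_planted_days_3_to_9_recovered(self):
        days = (
            [_sparse_day() for _ in range(2)]
            + [_alternating_day() for _ in range(7)]
            + [_sparse_day() for _ in range(3)]
        )
        w = select_wear_window(series_from_days(days))
        assert (w.start_date, w.end_date) == (D0 + timedelta(days=2), D0 + timedelta(days=8))
        assert w.n_days == 7
        assert w.method == "algorithm"

    def test_nine_wear_days_richest_stretch_wins(self):
        # days 2-8 (0-based 1..7) have uninterrupted wear; day 1 and day 9
        # carry 3-h planted non-wear blocks, so the middle 7 days are richest
        days = (
            [_day_with_zero_block(600, 180)]
            + [_alternating_day() for _ in range(7)]
            + [_day_with_zero_block(600, 180)]
        )
        w, profiles = detect_wear_window(series_from_days(days))
        assert (w.start_date, w.end_date) == (D0 + timedelta(days=1), D0 + timedelta(days=7))
        assert w.total_wear_hours == pytest.approx(7 * 24.0)
        assert profiles[0].choi_wear_minutes == pytest.approx(1440 - 180)

    def test_figure_like_partial_first_day(self):
        # 12-day signal: partial wear from 07:00 on day 5, full wear days
        # 6-11, nothing elsewhere -> a 7-day window from day 5 to day 11
        lead = 7 * 240  # 7 h of leading zeros at 15 s
        partial = day_epochs((EPD_15 - lead) // 2, lead_zero=lead, alternate=True)
        days = (
            [_sparse_day(50) for _ in range(4)]
            + [partial]
            + [_alternating_day() for _ in range(6)]
            + [_sparse_day(50)]
        )
        w = select_wear_window(series_from_days(days))
        assert (w.start_date, w.end_date) == (D0 + timedelta(days=4), D0 + timedelta(days=10))
        assert w.n_days == 7

    def test_partial_first_day_beyond_8h_dropped(self):
        # same layout but wear starts at 09:00 -> leading 9 h > 8 h, so the
        # window is the remaining 6 full days
        lead = 9 * 240
        partial = day_epochs((EPD_15 - lead) // 2, lead_zero=lead, alternate=True)
        days = [partial] + [_alternating_day() for _ in range(6)] + [_sparse_day(50)]
        w = select_wear_window(series_from_days(days))
        assert (w.start_date, w.end_date) == (D0 + timedelta(days=1), D0 + timedelta(days=6))
        assert w.n_days == 6

    def test_longest_run_chosen_over_earlier_shorter(self):
        days = (
            [_alternating_day() for _ in range(2)]
            + [_sparse_day()]
            + [_alternating_day() for _ in range(4)]
            + [_sparse_day()]
        )
        w = select_wear_window(series_from_days(days))
        assert (w.start_date, w.end_date) == (D0 + timedelta(days=3), D0 + timedelta(days=6))

    def test_short_circuit_ignores_choi_parameters(self):
        days = [_sparse_day()] + [_alternating_day() for _ in range(5)] + [_sparse_day()]
        s = series_from_days(days)
        base = select_wear_window(s)
        for choi in (
            ChoiParams(1, 0, 0),
            ChoiParams(600, 4, 60),
            ChoiParams(90, 0, 5),
        ):
            w = select_wear_window(s, AlgorithmConfig(choi=choi))
            assert (w.start_date, w.end_date, w.n_days) == (
                base.start_date,
                base.end_date,
                base.n_days,
            )

    def test_optional_trailing_day_rule(self):
        # wear 09:30-on day 1, full days 2-5, wear until 14:00 on day 6:
        # default keeps the last day; the symmetric rule (10 h trailing
        # zeros > 8 h) drops it when switched on
        sched = ((((9.5, 24.0),),) + tuple(((0.0, 24.0),) for _ in range(4))
                 + (((0.0, 14.0),),))
        spec = SimulationSpec(
            n_calendar_days=6, wear_schedule=sched, seed=8, spike_rate_per_hour=0.0
        )
        sim = simulate_signal(spec)
        w_default = select_wear_window(sim.series)
        assert (w_default.n_days, w_default.end_date) == (5, D0 + timedelta(days=5))
        w_trim = select_wear_window(sim.series, AlgorithmConfig(trailing_day_rule=True))
        assert (w_trim.n_days, w_trim.end_date) == (4, D0 + timedelta(days=4))

    def test_matches_bruteforce_on_seeded_signals(self):
        rng = np.random.default_rng(2024)
        for _ in range(12):
            spec = _random_protocol_spec(rng)
            sim = simulate_signal(spec)
            fast = select_wear_window(sim.series)
            slow = select_wear_window_bruteforce(sim.series)
            assert (fast.start_date, fast.end_date, fast.n_days) == (
                slow.start_date,
                slow.end_date,
                slow.n_days,
            )
            if fast.n_days:
                assert fast.total_wear_hours == pytest.approx(slow.total_wear_hours)


def _random_protocol_spec(rng: np.random.Generator) -> SimulationSpec:
    """Randomized multi-day protocol at 60-s epochs for oracle comparisons."""
    n_days = int(rng.integers(3, 15))
    schedule = []
    for _ in range(n_days):
        kind = rng.random()
        if kind < 0.25:
            schedule.append(())
        elif kind < 0.45:
            a = float(rng.integers(0, 80)) / 4.0
            b = float(rng.integers(int(a * 4) + 1, 97)) / 4.0
            schedule.append(((a, b),))
        else:
            schedule.append(((0.0, 24.0),))
    return SimulationSpec(
        n_calendar_days=n_days,
        epoch_length=60,
        wear_schedule=tuple(schedule),
        p_zero_during_wear=float(rng.uniform(0.2, 0.7)),
        spike_rate_per_hour=float(rng.uniform(0.0, 3.0)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


class TestWearWindowType:
    def test_invariants(self):
        with pytest.raises(ConfigError):
            WearWindow(D0, D0 + timedelta(days=6), 6)  # n_days mismatch
        with pytest.raises(ConfigError):
            WearWindow(D0, None, 3)
        with pytest.raises(ConfigError):
            WearWindow(None, None, 0, method="nonsense")
        w = WearWindow.from_dates(D0, D0 + timedelta(days=6))
        assert w.n_days == 7 and len(w.dates) == 7

    def test_json_roundtrip(self):
        w = WearWindow.from_dates(D0, D0 + timedelta(days=6), 150.5, "manual")
        assert window_from_dict(window_to_dict(w)) == w
        e = WearWindow.empty("log")
        assert window_from_dict(window_to_dict(e)) == e
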