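"""Shared builders for deterministic test signals."""

from __future__ import annotations

from datetime import date, datetime

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wearwindow import EpochSeries

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

EPD_15 = 86_400 // 15  # 5760 epochs per day at 15 s


def day_epochs(
    n_nonzero: int,
    epd: int = EPD_15,
    lead_zero: int = 0,
    value: int = 50,
    alternate: bool = False,
) -> np.ndarray:
    """One calendar day of tri-axial counts with an exact non-zero layout.

    Exactly ``n_nonzero`` epochs carry counts; the first ``lead_zero`` epochs
    are zero.  With ``alternate`` the non-zero epochs sit on every other slot
    after the lead (avoiding long zero runs the non-wear stage would flag);
    otherwise they are spread evenly over the remainder of the day.
    """
    day = np.zeros((epd, 3), dtype=np.int64)
    if n_nonzero == 0:
        return day
    avail = epd - lead_zero
    assert 0 < n_nonzero <= avail
    if alternate:
        assert n_nonzero <= (avail + 1) // 2
        idx = lead_zero + 2 * np.arange(n_nonzero)
    else:
        idx = lead_zero + np.unique(
            np.floor(np.linspace(0, avail - 1, n_nonzero)).astype(int)
        )
        assert idx.size == n_nonzero
    day[idx, 0] = value
    day[idx, 1] = value // 2
    return day


def series_from_days(
    day_arrays: list[np.ndarray],
    epoch_length: int = 15,
    start: date = date(2012, 3, 1),
) -> EpochSeries:
    """Stack per-day count blocks into a series starting at local midnight."""
    counts = np.concatenate(day_arrays, axis=0)
    return EpochSeries(
        datetime.combine(start, datetime.min.time()), epoch_length, counts
    )


@pytest.fixture
def d0() -> date:
    return date(2012, 3, 1)
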