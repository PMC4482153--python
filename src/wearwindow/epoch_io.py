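"""Epoch-level accelerometer count data: containers, CSV I/O, and day partitioning.

Hip-worn actigraphs (e.g. ActiGraph GT3X+) integrate raw accelerations into
non-negative integer movement "counts" per fixed-length epoch on three
orthogonal axes.  Everything downstream — non-wear classification, wear-window
selection — consumes these epoch counts, never the raw waveform.

Conventions
-----------
* Timestamps are timezone-naive local clock time; a calendar "day" is
  midnight to 11:59 PM of the local date, and daylight-saving shifts are not
  modeled.
* A series is contiguous by construction: epoch ``i`` covers
  ``[start_time + i*epoch_length, start_time + (i+1)*epoch_length)``.
  Gaps or duplicate timestamps in an input file are an error, never silently
  zero-filled — zero-filling would corrupt the non-zero-fraction day filter.
* "Non-zero epoch" means vector magnitude > 0 by default (equivalently, any
  axis non-zero); a vertical-axis-only interpretation is available via the
  ``axis`` argument of :func:`partition_days`.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "EpochSeries",
    "DayProfile",
    "EpochFormatError",
    "ContiguityError",
    "ConfigError",
    "read_epoch_csv",
    "write_epoch_csv",
    "vector_magnitude",
    "reepoch",
    "partition_days",
    "slice_dates",
]

SECONDS_PER_DAY = 86_400


class EpochFormatError(ValueError):
    """Malformed epoch count data (negative, non-integer, wrong shape)."""


class ContiguityError(EpochFormatError):
    """Gap or duplicate in per-row timestamps of an epoch file."""


class ConfigError(ValueError):
    """Missing or inconsistent configuration (epoch length, start time ...)."""


def _check_epoch_length(epoch_length: int) -> int:
    epoch_length = int(epoch_length)
    if epoch_length <= 0:
        raise ConfigError(f"epoch_length must be positive, got {epoch_length}")
    if 60 % epoch_length != 0 and epoch_length % 60 != 0:
        raise ConfigError(
            f"epoch_length {epoch_length} s is incompatible with exact "
            "re-epoching to 60 s (must divide 60 or be a multiple of 60)"
        )
    return epoch_length


@dataclass(frozen=True)
class EpochSeries:
    """Contiguous tri-axial epoch count series with an absolute start time.

    Parameters
    ----------
    start_time
        Timezone-naive local timestamp of the first epoch's left edge.
    epoch_length
        Epoch duration in seconds; must divide 60 or be a multiple of 60 so
        that re-epoching to one-minute epochs is exact.
    counts
        Integer array of shape ``(n, 3)``; columns are the device axes
        (axis 0 = vertical in the usual hip-worn orientation).
    device_id
        Opaque device/participant identifier carried through I/O.
    """

    start_time: datetime
    epoch_length: int
    counts: np.ndarray
    device_id: str | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[1] != 3 or counts.shape[0] < 1:
            raise EpochFormatError(
                f"counts must have shape (n>=1, 3), got {counts.shape}"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.mod(counts, 1) == 0):
                raise EpochFormatError("counts must be integral")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise EpochFormatError("counts must be non-negative")
        object.__setattr__(self, "counts", np.ascontiguousarray(counts, dtype=np.int64))
        object.__setattr__(self, "epoch_length", _check_epoch_length(self.epoch_length))
        if not isinstance(self.start_time, datetime):
            object.__setattr__(self, "start_time", pd.Timestamp(self.start_time).to_pydatetime())
        if self.start_time.tzinfo is not None:
            raise ConfigError("start_time must be timezone-naive local time")

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def counts_x(self) -> np.ndarray:
        return self.counts[:, 0]

    @property
    def counts_y(self) -> np.ndarray:
        return self.counts[:, 1]

    @property
    def counts_z(self) -> np.ndarray:
        return self.counts[:, 2]

    @property
    def end_time(self) -> datetime:
        """Right edge of the last epoch (exclusive)."""
        return self.start_time + timedelta(seconds=len(self) * self.epoch_length)

    def timestamps(self) -> pd.DatetimeIndex:
        """Left-edge timestamp of every epoch."""
        return pd.date_range(
            self.start_time, periods=len(self), freq=pd.Timedelta(seconds=self.epoch_length)
        )

    def epoch_dates(self) -> np.ndarray:
        """Calendar date index (days since the first date) of every epoch."""
        offset = int((self.start_time - datetime.combine(self.start_time.date(), datetime.min.time())).total_seconds())
        secs = offset + np.arange(len(self), dtype=np.int64) * self.epoch_length
        return secs // SECONDS_PER_DAY


@dataclass
class DayProfile:
    """Per-calendar-day summary used by the day filter.

    ``fraction_nonzero`` uses the actual number of recorded epochs in the day
    as denominator (a partial first/last day is judged on what was recorded,
    not a nominal 86 400 s).  ``choi_wear_minutes`` is ``None`` until the
    non-wear stage has run over the day.
    """

    date: date
    first_epoch_index: int
    n_epochs: int
    fraction_nonzero: float
    leading_zero_hours: float
    choi_wear_minutes: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_nonzero <= 1.0):
            raise EpochFormatError("fraction_nonzero must lie in [0, 1]")
        if self.leading_zero_hours < 0:
            raise EpochFormatError("leading_zero_hours must be >= 0")


def vector_magnitude(series: EpochSeries) -> np.ndarray:
    """Per-epoch Euclidean norm sqrt(x**2 + y**2 + z**2) of the axis counts."""
    c = series.counts.astype(np.float64)
    return np.sqrt(np.einsum("ij,ij->i", c, c))


def reepoch(series: EpochSeries, target: int) -> EpochSeries:
    """Aggregate to a longer epoch by per-axis summation.

    ``target`` must be an integer multiple of the series' epoch length; a
    trailing partial block is dropped.  Counts are additive over time, so
    per-axis sums reproduce what the device would have exported at the coarser
    epoch setting.
    """
    target = int(target)
    if target <= 0 or target % series.epoch_length != 0:
        raise ConfigError(
            f"target epoch {target} s is not a multiple of {series.epoch_length} s"
        )
    k = target // series.epoch_length
    if k == 1:
        return series
    n_out = len(series) // k
    if n_out == 0:
        raise ConfigError("series shorter than one target epoch")
    summed = series.counts[: n_out * k].reshape(n_out, k, 3).sum(axis=1)
    return EpochSeries(series.start_time, target, summed, device_id=series.device_id)


def partition_days(series: EpochSeries, axis: str = "vm") -> list[DayProfile]:
    """Split a series into per-calendar-date profiles (midnight to 11:59 PM).

    Parameters
    ----------
    series
        The epoch series to partition.
    axis
        ``"vm"`` judges an epoch non-zero by vector magnitude > 0 (any axis
        active); ``"vertical"`` uses the vertical axis only.

    Returns one :class:`DayProfile` per calendar date touched by the series,
    in date order; together they cover every epoch exactly once.
    """
    if axis == "vm":
        nonzero = series.counts.any(axis=1)
    elif axis == "vertical":
        nonzero = series.counts[:, 0] > 0
    else:
        raise ConfigError(f"axis must be 'vm' or 'vertical', got {axis!r}")

    day_idx = series.epoch_dates()
    first_date = series.start_time.date()
    profiles: list[DayProfile] = []
    # day_idx is sorted; find block boundaries
    boundaries = np.flatnonzero(np.diff(day_idx)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(series)]))
    for s, e in zip(starts, ends):
        nz = nonzero[s:e]
        n = int(e - s)
        lead = int(np.argmax(nz)) if nz.any() else n
        profiles.append(
            DayProfile(
                date=first_date + timedelta(days=int(day_idx[s])),
                first_epoch_index=int(s),
                n_epochs=n,
                fraction_nonzero=float(np.count_nonzero(nz)) / n,
                leading_zero_hours=lead * series.epoch_length / 3600.0,
            )
        )
    return profiles


def slice_dates(series: EpochSeries, start: date, end: date) -> EpochSeries:
    """Sub-series of all epochs whose calendar date lies in ``[start, end]``."""
    if end < start:
        raise ConfigError("end date before start date")
    first_date = series.start_time.date()
    lo = (start - first_date).days
    hi = (end - first_date).days
    day_idx = series.epoch_dates()
    keep = (day_idx >= lo) & (day_idx <= hi)
    if not keep.any():
        raise ConfigError(f"series does not touch dates {start}..{end}")
    i0 = int(np.argmax(keep))
    i1 = len(keep) - int(np.argmax(keep[::-1]))
    new_start = series.start_time + timedelta(seconds=i0 * series.epoch_length)
    return EpochSeries(new_start, series.epoch_length, series.counts[i0:i1],
                       device_id=series.device_id)


# ---------------------------------------------------------------------------
# Epoch CSV dialect
#
# Header variant (written by write_epoch_csv, read leniently):
#
#     ------------ epoch count export ------------
#     Start Date 2012-03-01
#     Start Time 00:00:00
#     Epoch Period (hh:mm:ss) 00:00:15
#     Device ID sim001
#     --------------------------------------------
#     timestamp,x,y,z
#     2012-03-01T00:00:00,0,0,0
#
# Only the start time and epoch length are required from a preamble; the
# labels follow the common ActiGraph epoch-export layout.  The headerless
# variant is bare "x,y,z" (or "timestamp,x,y,z") rows with start time /
# epoch length supplied by the caller.
# ---------------------------------------------------------------------------

_PREAMBLE_RES = {
    "start_date": re.compile(r"start date[:\s]+(\S+)", re.I),
    "start_time": re.compile(r"start time[:\s]+(\d{1,2}:\d{2}:\d{2})", re.I),
    "epoch_hms": re.compile(r"epoch period.*?(\d+):(\d{2}):(\d{2})", re.I),
    "epoch_s": re.compile(r"epoch length\s*\(s\)[:\s]+(\d+)", re.I),
    "device": re.compile(r"device id[:\s]+(\S+)", re.I),
}

_NUM = r"-?\d+(?:\.\d+)?"
_DATA_ROW_RE = re.compile(
    rf"^\s*(\d{{4}}-\d{{2}}-\d{{2}}[T ][\d:.]+\s*,)?\s*{_NUM}\s*,\s*{_NUM}\s*,\s*{_NUM}\s*$"
)


def _parse_date(text: str) -> date:
    for fmt in ("%Y-%m-%d", "%m/%d/%Y", "%d/%m/%Y"):
        try:
            return datetime.strptime(text, fmt).date()
        except ValueError:
            continue
    raise EpochFormatError(f"unparseable date {text!r} in preamble")


def read_epoch_csv(
    path,
    *,
    epoch_length: int | None = None,
    start_time: datetime | None = None,
    device_id: str | None = None,
) -> EpochSeries:
    """Read an epoch count CSV (header or headerless dialect) into a series.

    The dialect is auto-detected: a metadata preamble supplies start time and
    epoch length; otherwise per-row timestamps or the ``epoch_length`` /
    ``start_time`` arguments must determine them.  Per-row timestamps, when
    present, are validated for contiguity — a gap or duplicate raises
    :class:`ContiguityError` rather than being zero-filled.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    meta: dict[str, object] = {}
    data_start = 0
    for i, line in enumerate(lines):
        if _DATA_ROW_RE.match(line):
            data_start = i
            break
        for key, rx in _PREAMBLE_RES.items():
            m = rx.search(line)
            if m:
                meta[key] = m
        # tolerate a column-header row
    else:
        raise EpochFormatError(f"no data rows found in {path}")

    if "start_date" in meta and "start_time" in meta and start_time is None:
        d = _parse_date(meta["start_date"].group(1))
        hh, mm, ss = (int(v) for v in meta["start_time"].group(1).split(":"))
        start_time = datetime.combine(d, datetime.min.time()) + timedelta(
            hours=hh, minutes=mm, seconds=ss
        )
    if epoch_length is None:
        if "epoch_hms" in meta:
            h, m, s = (int(g) for g in meta["epoch_hms"].groups())
            epoch_length = h * 3600 + m * 60 + s
        elif "epoch_s" in meta:
            epoch_length = int(meta["epoch_s"].group(1))
    if device_id is None and "device" in meta:
        device_id = meta["device"].group(1)

    body = "\n".join(lines[data_start:])
    df = pd.read_csv(io.StringIO(body), header=None)
    if df.shape[1] == 4:
        ts = pd.to_datetime(df.iloc[:, 0], format="ISO8601")
        counts = df.iloc[:, 1:4]
        deltas = np.diff(ts.to_numpy().astype("datetime64[s]").astype(np.int64))
        if epoch_length is None:
            if len(deltas) == 0:
                raise ConfigError(
                    "single-row timestamped file: epoch_length must be given"
                )
            epoch_length = int(deltas[0])
        if len(deltas) and not np.all(deltas == epoch_length):
            bad = int(np.flatnonzero(deltas != epoch_length)[0])
            raise ContiguityError(
                f"timestamp step of {int(deltas[bad])} s at row {bad + 1} "
                f"(expected {epoch_length} s): gaps/duplicates are not zero-filled"
            )
        if start_time is None:
            start_time = ts.iloc[0].to_pydatetime()
        elif pd.Timestamp(start_time) != ts.iloc[0]:
            raise ContiguityError(
                f"first row timestamp {ts.iloc[0]} disagrees with declared start {start_time}"
            )
    elif df.shape[1] == 3:
        counts = df
        if epoch_length is None:
            raise ConfigError(
                "headerless file without timestamps: epoch_length is required"
            )
        if start_time is None:
            raise ConfigError(
                "headerless file without timestamps: start_time is required"
            )
    else:
        raise EpochFormatError(
            f"expected 3 or 4 columns, found {df.shape[1]} in {path}"
        )

    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        raise EpochFormatError("counts must be non-negative integers")
    return EpochSeries(start_time, int(epoch_length), arr, device_id=device_id)


def write_epoch_csv(series: EpochSeries, path, *, timestamps: bool = True) -> None:
    """Write a series in the header dialect (deterministic byte-for-byte)."""
    eplen = series.epoch_length
    hms = f"{eplen // 3600:02d}:{eplen % 3600 // 60:02d}:{eplen % 60:02d}"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("------------ epoch count export ------------\n")
        fh.write(f"Start Date {series.start_time.date().isoformat()}\n")
        fh.write(f"Start Time {series.start_time.strftime('%H:%M:%S')}\n")
        fh.write(f"Epoch Period (hh:mm:ss) {hms}\n")
        if series.device_id is not None:
            fh.write(f"Device ID {series.device_id}\n")
        fh.write("--------------------------------------------\n")
        if timestamps:
            stamps = series.timestamps().strftime("%Y-%m-%dT%H:%M:%S")
            body = pd.DataFrame(
                {
                    "t": stamps,
                    "x": series.counts_x,
                    "y": series.counts_y,
                    "z": series.counts_z,
                }
            )
        else:
            body = pd.DataFrame(
                {"x": series.counts_x, "y": series.counts_y, "z": series.counts_z}
            )
        body.to_csv(fh, header=False, index=False, lineterminator="\n")
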