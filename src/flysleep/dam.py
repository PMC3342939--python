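"""Reading, writing and annotating Drosophila Activity Monitor (DAM) data.

The DAM system reports infrared-beam crossings per channel (one fly per
channel, 32 channels per monitor) in fixed one-minute bins.  This module
parses monitor files into per-reading records, assembles per-fly
:class:`ActivitySeries` with photoperiod annotation, and writes monitor
files back out so that synthetic experiments round-trip exactly.

Two on-disk dialects are supported:

``monitor``
    Tab-delimited, one row per reading: reading index, date (``dd Mon yy``),
    time (``HH:MM:SS``), status code, six reserved columns, then 32 count
    columns.  Status ``1`` marks a valid reading; any other status
    invalidates that minute for every channel.

``long``
    A portable CSV with header ``timestamp,channel,count`` for interchange
    with other tools.

Missing minutes are represented as NaN in :class:`ActivitySeries.counts`
and are never silently zero-filled: a zero is biologically meaningful
(inactivity), a gap is not.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from datetime import datetime, time, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, OrderingError, ParseError, QualityError

N_CHANNELS = 32
STATUS_OK = 1
MINUTES_PER_DAY = 1440
HALF_DAY = 720

#: Supported lighting regimes: 12h:12h light:dark, constant light, constant dark.
REGIMES = ("LD12:12", "LL", "DD")

_DATE_FMT = "%d %b %y"
_TIME_FMT = "%H:%M:%S"


@dataclass(frozen=True)
class DamReading:
    """One monitor row: a timestamped vector of 32 per-channel counts."""

    index: int
    timestamp: datetime
    status: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (N_CHANNELS,):
            raise ValueError(f"counts must have length {N_CHANNELS}, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)


@dataclass
class ActivitySeries:
    """One fly's per-minute beam-cross counts, clock-anchored.

    ``counts[i]`` is the number of beam crossings in minute
    ``start_time + i``; NaN marks a missing or invalidated minute.
    ``light_state[i]`` is True during the light (day) phase, derived from
    the lighting regime and the lights-on clock time (ZT0).
    """

    fly_id: str
    start_time: datetime
    counts: np.ndarray
    regime: str = "LD12:12"
    lights_on: time = time(8, 0)

    bin_minutes = 1

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}, got {self.regime!r}")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.counts, initial=0) < 0:
                raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return self.counts.size

    @property
    def minute_of_day(self) -> np.ndarray:
        """Clock minute-of-day (0..1439) for each bin."""
        start = self.start_time.hour * 60 + self.start_time.minute
        return (start + np.arange(len(self))) % MINUTES_PER_DAY

    @property
    def light_state(self) -> np.ndarray:
        """Boolean per-minute day/night labels (True = lights on)."""
        if self.regime == "LL":
            return np.ones(len(self), dtype=bool)
        if self.regime == "DD":
            return np.zeros(len(self), dtype=bool)
        on = self.lights_on.hour * 60 + self.lights_on.minute
        zt = (self.minute_of_day - on) % MINUTES_PER_DAY
        return zt < HALF_DAY

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.counts)

    @property
    def n_missing(self) -> int:
        return int(self.missing.sum())

    def timestamps(self) -> list[datetime]:
        return [self.start_time + timedelta(minutes=int(i)) for i in range(len(self))]


def _parse_monitor_line(line: str, lineno: int) -> DamReading:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 10 + N_CHANNELS:
        raise ParseError(f"line {lineno}: expected {10 + N_CHANNELS} columns, got {len(parts)}")
    try:
        idx = int(parts[0])
        ts = datetime.strptime(f"{parts[1].strip()} {parts[2].strip()}", f"{_DATE_FMT} {_TIME_FMT}")
        status = int(parts[3])
        counts = np.array([int(c) for c in parts[10:10 + N_CHANNELS]], dtype=np.int64)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from None
    if (counts < 0).any():
        raise ParseError(f"line {lineno}: negative count")
    return DamReading(index=idx, timestamp=ts, status=status, counts=counts)


def _read_long(path) -> list[DamReading]:
    frame: dict[datetime, np.ndarray] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != ["timestamp", "channel", "count"]:
            raise ParseError("long dialect requires header 'timestamp,channel,count'")
        for lineno, row in enumerate(reader, start=2):
            try:
                ts = datetime.fromisoformat(row[0])
                channel = int(row[1])
                count = int(row[2])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
            if not 1 <= channel <= N_CHANNELS:
                raise ParseError(f"line {lineno}: channel {channel} out of range 1..{N_CHANNELS}")
            if count < 0:
                raise ParseError(f"line {lineno}: negative count")
            frame.setdefault(ts, np.zeros(N_CHANNELS, dtype=np.int64))[channel - 1] = count
    return [
        DamReading(index=i + 1, timestamp=ts, status=STATUS_OK, counts=frame[ts])
        for i, ts in enumerate(sorted(frame))
    ]


def read_dam(path, dialect: str = "monitor") -> list[DamReading]:
    """Read a monitor file, returning readings sorted by timestamp.

    Duplicate timestamps are rejected (:class:`OrderingError`); gaps are
    tolerated here and reported by :func:`scan_gaps` /
    :func:`extract_series`.
    """
    if dialect == "monitor":
        readings = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.strip():
                    readings.append(_parse_monitor_line(line, lineno))
    elif dialect == "long":
        readings = _read_long(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    readings.sort(key=lambda r: r.timestamp)
    for a, b in zip(readings, readings[1:]):
        if a.timestamp == b.timestamp:
            raise OrderingError(f"duplicate timestamp {a.timestamp.isoformat()}")
    return readings


def scan_gaps(readings: Sequence[DamReading]) -> list[tuple[datetime, datetime, int]]:
    """Report monitor dropouts as (last seen, next seen, minutes missing)."""
    gaps = []
    for a, b in zip(readings, readings[1:]):
        dt = int((b.timestamp - a.timestamp).total_seconds() // 60)
        if dt > 1:
            gaps.append((a.timestamp, b.timestamp, dt - 1))
    return gaps


def extract_series(
    readings: Sequence[DamReading],
    channel: int,
    regime: str = "LD12:12",
    lights_on: time = time(8, 0),
    fly_id: str | None = None,
    max_missing_frac: float = 0.05,
) -> ActivitySeries:
    """Assemble one channel into a clock-anchored per-minute series.

    Minutes absent from the file, or carried by readings with a non-OK
    status code, become NaN.  If more than ``max_missing_frac`` of minutes
    are missing the channel fails QC with :class:`QualityError`.
    """
    if not 1 <= channel <= N_CHANNELS:
        raise ValueError(f"channel must be in 1..{N_CHANNELS}")
    if not readings:
        raise ValueError("no readings")
    start = readings[0].timestamp
    n_min = int((readings[-1].timestamp - start).total_seconds() // 60) + 1
    counts = np.full(n_min, np.nan)
    for r in readings:
        i = int((r.timestamp - start).total_seconds() // 60)
        if r.status == STATUS_OK:
            counts[i] = r.counts[channel - 1]
    missing_frac = np.isnan(counts).mean()
    if missing_frac > max_missing_frac:
        raise QualityError(
            f"channel {channel}: {missing_frac:.1%} of minutes missing "
            f"(limit {max_missing_frac:.1%})"
        )
    return ActivitySeries(
        fly_id=fly_id or f"ch{channel:02d}",
        start_time=start,
        counts=counts,
        regime=regime,
        lights_on=lights_on,
    )


def trim_acclimation(series: ActivitySeries, discard_days: int = 1) -> ActivitySeries:
    """Drop the first ``discard_days`` full days (acclimation after loading)."""
    if discard_days < 0:
        raise ValueError("discard_days must be >= 0")
    cut = discard_days * MINUTES_PER_DAY
    if cut >= len(series) and discard_days > 0:
        raise ValueError(
            f"cannot discard {discard_days} day(s) from a {len(series)}-minute series"
        )
    if cut == 0:
        return replace(series, counts=series.counts.copy())
    return replace(
        series,
        counts=series.counts[cut:].copy(),
        start_time=series.start_time + timedelta(minutes=cut),
    )


def write_dam(series_by_channel: Mapping[int, ActivitySeries], path, start_index: int = 1) -> None:
    """Write per-channel series as a monitor-dialect file.

    All series must share start time and length; unused channels are
    written as zeros.  Missing minutes cannot be represented in this
    dialect and raise ``ValueError``.
    """
    if not series_by_channel:
        raise ValueError("no series to write")
    if len(series_by_channel) > N_CHANNELS:
        raise ValueError(f"at most {N_CHANNELS} channels, got {len(series_by_channel)}")
    for ch in series_by_channel:
        if not 1 <= ch <= N_CHANNELS:
            raise ValueError(f"channel {ch} out of range 1..{N_CHANNELS}")
    first = next(iter(series_by_channel.values()))
    n = len(first)
    for ch, s in series_by_channel.items():
        if len(s) != n or s.start_time != first.start_time:
            raise ValueError(f"channel {ch}: start time or length mismatch")
        if s.missing.any():
            raise ValueError(f"channel {ch}: monitor dialect cannot represent missing minutes")
    table = np.zeros((n, N_CHANNELS), dtype=np.int64)
    for ch, s in series_by_channel.items():
        table[:, ch - 1] = s.counts.astype(np.int64)
    with open(path, "w") as fh:
        ts = first.start_time
        for i in range(n):
            stamp = ts + timedelta(minutes=i)
            row = [
                str(start_index + i),
                stamp.strftime(_DATE_FMT),
                stamp.strftime(_TIME_FMT),
                str(STATUS_OK),
            ] + ["0"] * 6 + [str(c) for c in table[i]]
            fh.write("\t".join(row) + "\n")


def write_long(series_by_channel: Mapping[int, ActivitySeries], path) -> None:
    """Write the portable long-format CSV (timestamp,channel,count)."""
    first = next(iter(series_by_channel.values()))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["timestamp", "channel", "count"])
        for ch in sorted(series_by_channel):
            s = series_by_channel[ch]
            for i, c in enumerate(s.counts):
                if not np.isnan(c):
                    stamp = first.start_time + timedelta(minutes=i)
                    writer.writerow([stamp.isoformat(), ch, int(c)])


DESIGN_COLUMNS = [
    "monitor_id", "channel", "fly_id", "genotype", "diet",
    "sex", "cohort", "is_control", "regime",
]


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Validate an experiment-design table (factor assignments per channel).

    Requires the documented columns, unique (monitor_id, channel) keys,
    and at least one control fly in every cohort (the control group
    anchors partitioning-score normalization).
    """
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise DesignError(f"design table missing columns: {missing}")
    design = design.copy()
    if design["is_control"].dtype != bool:
        design["is_control"] = (
            design["is_control"].astype(str).str.strip().str.lower()
            .map({"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False})
        )
        if design["is_control"].isna().any():
            raise DesignError("is_control must be boolean")
    dup = design.duplicated(subset=["monitor_id", "channel"])
    if dup.any():
        raise DesignError(f"duplicate (monitor_id, channel) keys at rows {list(design.index[dup])}")
    if design["fly_id"].duplicated().any():
        raise DesignError("fly_id values must be unique")
    for cohort, grp in design.groupby("cohort"):
        if not grp["is_control"].any():
            raise DesignError(f"cohort {cohort!r} has no control flies")
    bad = set(design["regime"]) - set(REGIMES)
    if bad:
        raise DesignError(f"unknown regimes {sorted(bad)}")
    return design


def read_design(path) -> pd.DataFrame:
    return validate_design(pd.read_csv(path))


def write_design(design: pd.DataFrame, path) -> None:
    validate_design(design).to_csv(path, index=False, columns=DESIGN_COLUMNS)
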