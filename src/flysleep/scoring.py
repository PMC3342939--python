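"""Sleep-bout scoring and per-fly architecture metrics.

Fly sleep is scored from per-minute beam-cross counts with the
field-standard inactivity definition: a *sleep bout* is a maximal run of
at least five consecutive minutes with zero counts.  Shorter inactivity
runs (1-4 min) are *rest*; runs of minutes with at least one count are
*wake*, and an isolated one-minute wake run between inactive periods is a
*brief awakening*.  All intervals are half-open ``[start, end)`` in
minutes since the start of the series.

Conventions chosen where the literature is silent (see the methods note):

* Bouts touching the recording boundary or a monitor dropout are flagged
  ``censored``; they count toward totals but are excluded from bout-length
  distributions, whose tails would otherwise be truncated.
* Bouts spanning a lights transition are split at the transition for
  day/night metrics but counted once (phase ``mixed``) in whole-recording
  bout counts, so day and night totals stay additive without
  double-counting.
* Waking activity is total counts divided by minutes *not inside a sleep
  bout* (rest minutes are waking minutes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dam import HALF_DAY, MINUTES_PER_DAY, ActivitySeries

SLEEP_MIN = 5  # minimum inactivity run length (minutes) that counts as sleep


@dataclass(frozen=True)
class Bout:
    """A maximal run of one behavioral kind, half-open in minutes."""

    start: int
    end: int
    kind: str  # sleep | rest | wake
    phase: str  # day | night | mixed
    censored: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PeriodMetrics:
    """Architecture metrics for one analysis period (whole/day/night)."""

    minutes: int
    total_sleep_min: float
    sleep_bout_count: int
    mean_bout_length_min: float
    rest_count: int
    brief_awakening_count: int
    waking_activity: float


@dataclass
class SleepRecord:
    """Per-fly summary: whole-recording plus day and night metrics."""

    fly_id: str
    whole: PeriodMetrics
    day: PeriodMetrics
    night: PeriodMetrics
    latency_after_lights_on_min: float | None = None
    latency_after_lights_off_min: float | None = None
    death_time_min: int | None = None

    def to_dict(self) -> dict:
        row: dict = {"fly_id": self.fly_id}
        for period in ("whole", "day", "night"):
            m: PeriodMetrics = getattr(self, period)
            for k, v in vars(m).items():
                row[f"{period}_{k}"] = v
        row["latency_after_lights_on_min"] = self.latency_after_lights_on_min
        row["latency_after_lights_off_min"] = self.latency_after_lights_off_min
        row["death_time_min"] = self.death_time_min
        return row


def _segments(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal label as (start, end, label)."""
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [(int(s), int(e), int(labels[s])) for s, e in zip(starts, ends)]


def _phase_of(light: np.ndarray, start: int, end: int) -> str:
    seg = light[start:end]
    if seg.all():
        return "day"
    if not seg.any():
        return "night"
    return "mixed"


def find_runs(series: ActivitySeries) -> list[Bout]:
    """Classify the series into maximal sleep / rest / wake bouts.

    Missing minutes are treated as gaps: they produce no bout, and the
    bouts adjacent to a gap (or to the recording boundary) are censored.
    The returned bouts tile the series apart from gaps.
    """
    counts = series.counts
    if counts.size == 0:
        return []
    # 0 = inactive, 1 = active, 2 = missing
    labels = np.where(np.isnan(counts), 2, (np.nan_to_num(counts) > 0).astype(int))
    light = series.light_state
    bouts: list[Bout] = []
    segs = _segments(labels)
    for i, (s, e, lab) in enumerate(segs):
        if lab == 2:
            continue
        kind = "wake" if lab == 1 else ("sleep" if e - s >= SLEEP_MIN else "rest")
        censored = (
            s == 0
            or e == counts.size
            or (i > 0 and segs[i - 1][2] == 2)
            or (i + 1 < len(segs) and segs[i + 1][2] == 2)
        )
        bouts.append(Bout(s, e, kind, _phase_of(light, s, e), censored))
    return bouts


def split_at_transitions(bouts: Iterable[Bout], series: ActivitySeries) -> list[Bout]:
    """Split bouts at lights transitions; pieces keep their parent's kind."""
    light = series.light_state
    out: list[Bout] = []
    for b in bouts:
        if b.phase != "mixed":
            out.append(b)
            continue
        for s, e, lab in _segments(light[b.start:b.end].astype(int)):
            out.append(
                Bout(b.start + s, b.start + e, b.kind, "day" if lab else "night", b.censored)
            )
    return out


def sleep_mask(series: ActivitySeries, bouts: Sequence[Bout] | None = None) -> np.ndarray:
    """Boolean per-minute indicator of being inside a sleep bout."""
    if bouts is None:
        bouts = find_runs(series)
    mask = np.zeros(len(series), dtype=bool)
    for b in bouts:
        if b.kind == "sleep":
            mask[b.start:b.end] = True
    return mask


def _period_metrics(
    series: ActivitySeries,
    bouts: Sequence[Bout],
    pieces: Sequence[Bout],
    minute_sel: np.ndarray,
    phase: str | None,
) -> PeriodMetrics:
    counts = series.counts
    asleep = sleep_mask(series, bouts)
    sel = minute_sel & ~np.isnan(counts)
    n_min = int(minute_sel.sum())
    total_sleep = int((asleep & minute_sel).sum())
    if phase is None:
        sleep_bouts = [b for b in bouts if b.kind == "sleep"]
        rest = [b for b in bouts if b.kind == "rest"]
        brief = [b for b in bouts if b.kind == "wake" and b.length == 1 and not b.censored]
    else:
        sleep_bouts = [b for b in pieces if b.kind == "sleep" and b.phase == phase]
        rest = [b for b in pieces if b.kind == "rest" and b.phase == phase]
        brief = [
            b for b in pieces
            if b.kind == "wake" and b.length == 1 and not b.censored and b.phase == phase
        ]
    n_bouts = len(sleep_bouts)
    mean_len = float(np.mean([b.length for b in sleep_bouts])) if n_bouts else math.nan
    waking_min = sel & ~asleep
    denom = int(waking_min.sum())
    waking_activity = float(np.nansum(counts[waking_min]) / denom) if denom else math.nan
    return PeriodMetrics(
        minutes=n_min,
        total_sleep_min=float(total_sleep),
        sleep_bout_count=n_bouts,
        mean_bout_length_min=mean_len,
        rest_count=len(rest),
        brief_awakening_count=len(brief),
        waking_activity=waking_activity,
    )


def score_sleep(series: ActivitySeries, latencies: bool = True) -> SleepRecord:
    """Compute the per-fly architecture summary.

    Metrics are reported for the whole recording and separately for the
    day and night phase.  Under LD, latencies after lights-on and
    lights-off are averaged over all complete transitions in the
    recording; under LL/DD they are left unset.
    """
    if np.isnan(series.counts).all():
        raise ValueError("series is entirely missing")
    bouts = find_runs(series)
    pieces = split_at_transitions(bouts, series)
    light = series.light_state
    all_min = np.ones(len(series), dtype=bool)
    record = SleepRecord(
        fly_id=series.fly_id,
        whole=_period_metrics(series, bouts, pieces, all_min, None),
        day=_period_metrics(series, bouts, pieces, light, "day"),
        night=_period_metrics(series, bouts, pieces, ~light, "night"),
        death_time_min=call_death(series),
    )
    if latencies and series.regime == "LD12:12":
        for attr, transition in (
            ("latency_after_lights_on_min", "lights_on"),
            ("latency_after_lights_off_min", "lights_off"),
        ):
            vals = [
                lat
                for i in range(len(transition_minutes(series, transition)))
                if (lat := sleep_latency(series, transition, i, _bouts=bouts)) is not None
            ]
            setattr(record, attr, float(np.mean(vals)) if vals else None)
    return record


def transition_minutes(series: ActivitySeries, transition: str) -> list[int]:
    """Minute indices at which the requested lighting transition occurs.

    The series start counts as a transition if it coincides with one.
    Only transitions with a full half-day of recording after them are
    returned, so latency windows are always complete.
    """
    if series.regime != "LD12:12":
        raise ValueError(f"no lighting transitions under regime {series.regime}")
    if transition not in ("lights_on", "lights_off"):
        raise ValueError("transition must be 'lights_on' or 'lights_off'")
    on = series.lights_on.hour * 60 + series.lights_on.minute
    target = on if transition == "lights_on" else (on + HALF_DAY) % MINUTES_PER_DAY
    idx = np.flatnonzero(series.minute_of_day == target)
    return [int(i) for i in idx if i + HALF_DAY <= len(series)]


def sleep_latency(
    series: ActivitySeries,
    transition: str = "lights_off",
    period_index: int = 0,
    _bouts: Sequence[Bout] | None = None,
) -> float | None:
    """Minutes from a lighting transition to the first sleep-bout onset.

    Returns None if no sleep bout starts before the next opposite
    transition (a fully active half-day).
    """
    marks = transition_minutes(series, transition)
    if not 0 <= period_index < len(marks):
        raise IndexError(f"period_index {period_index} out of range (have {len(marks)})")
    t0 = marks[period_index]
    bouts = find_runs(series) if _bouts is None else _bouts
    for b in bouts:
        if b.kind == "sleep" and t0 <= b.start < t0 + HALF_DAY:
            return float(b.start - t0)
    return None


def sleep_profile(series: ActivitySeries, window_min: int = 30) -> np.ndarray:
    """Circadian sleep profile: fraction asleep per minute of day.

    The per-minute asleep indicator is averaged over recording days, then
    smoothed with a centered moving window that wraps across the 24 h day
    (for even windows the extra minute goes before the center).  Missing
    minutes are ignored in both averages.
    """
    if not 1 <= window_min <= MINUTES_PER_DAY:
        raise ValueError("window_min must be in 1..1440")
    asleep = sleep_mask(series).astype(float)
    asleep[series.missing] = np.nan
    mod = series.minute_of_day
    sums = np.zeros(MINUTES_PER_DAY)
    cnts = np.zeros(MINUTES_PER_DAY)
    ok = ~np.isnan(asleep)
    np.add.at(sums, mod[ok], asleep[ok])
    np.add.at(cnts, mod[ok], 1)
    with np.errstate(invalid="ignore"):
        per_minute = sums / cnts
    valid = cnts > 0
    offsets = np.arange(-(window_min // 2), window_min - window_min // 2)
    num = np.zeros(MINUTES_PER_DAY)
    den = np.zeros(MINUTES_PER_DAY)
    for off in offsets:
        rolled = np.roll(per_minute, -off)
        rolled_ok = np.roll(valid, -off)
        num += np.where(rolled_ok, np.nan_to_num(rolled), 0.0)
        den += rolled_ok
    with np.errstate(invalid="ignore"):
        return num / den


def bout_length_distribution(
    bouts: Sequence[Bout], kind: str = "sleep", include_censored: bool = False
) -> pd.Series:
    """Empirical bout-length distribution (probability mass by length).

    Censored bouts are excluded by default because their observed lengths
    are truncated.
    """
    lengths = [
        b.length for b in bouts if b.kind == kind and (include_censored or not b.censored)
    ]
    if not lengths:
        raise ValueError(f"no {'' if include_censored else 'uncensored '}{kind} bouts")
    counts = pd.Series(lengths).value_counts().sort_index()
    dist = counts / counts.sum()
    dist.index.name = "length_min"
    dist.name = "mass"
    return dist


def call_death(series: ActivitySeries, quiescence_min: int = 720) -> int | None:
    """Death time from terminal quiescence (no counts for >= 12 h to the end).

    Returns the minute index one past the last active minute, or None if
    the fly is active within the final ``quiescence_min`` minutes.
    Missing minutes carry no evidence of activity and do not break the
    quiescent run.
    """
    active = np.flatnonzero(np.nan_to_num(series.counts) > 0)
    candidate = int(active[-1]) + 1 if active.size else 0
    if len(series) - candidate >= quiescence_min:
        return candidate
    return None


def records_to_frame(records: Iterable[SleepRecord]) -> pd.DataFrame:
    """Flatten SleepRecords into a per-fly metrics table."""
    return pd.DataFrame([r.to_dict() for r in records])


def bouts_to_frame(bouts_by_fly: dict[str, Sequence[Bout]]) -> pd.DataFrame:
    rows = [
        {"fly_id": fid, "start": b.start, "end": b.end, "kind": b.kind,
         "phase": b.phase, "censored": b.censored}
        for fid, bouts in bouts_by_fly.items()
        for b in bouts
    ]
    return pd.DataFrame(rows, columns=["fly_id", "start", "end", "kind", "phase", "censored"])
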