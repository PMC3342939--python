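"""Light-pulse arousal and sleep-deprivation/rebound analysis.

The arousal assay probes sleep depth: a 5-minute light pulse is delivered
one hour after lights-off (ZT13), when most flies are inside a sleep
bout.  Only flies asleep at pulse onset are eligible.  For each eligible
fly the assay reports the latency from pulse onset to the first active
minute, post-pulse activity in a configurable window, and a
*non-responder* flag: no activity for three hours after the pulse but
activity the following day, which distinguishes deep sleep from death.

Deprivation analysis quantifies the efficacy of a mechanical
sleep-deprivation window (fraction of baseline sleep lost) and the
rebound: extra sleep after deprivation relative to the identical
clock-time window a day earlier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dam import HALF_DAY, MINUTES_PER_DAY, ActivitySeries
from .scoring import call_death, sleep_mask, transition_minutes


@dataclass(frozen=True)
class PulseSpec:
    """Timing of a light-pulse arousal probe, in minutes since series start."""

    pulse_start: int
    pulse_duration_min: int = 5
    response_horizon_min: int = 180
    post_activity_window_min: int = 60

    def __post_init__(self) -> None:
        if self.pulse_start < 0:
            raise ValueError("pulse_start must be >= 0")
        for f in ("pulse_duration_min", "response_horizon_min", "post_activity_window_min"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


@dataclass
class ArousalResult:
    fly_id: str
    eligible: bool
    latency_min: float | None = None
    post_pulse_activity: float | None = None
    non_responder: bool | None = None  # None = censored or excluded (death)

    def to_dict(self) -> dict:
        return dict(vars(self))


def pulse_spec_for_night(
    series: ActivitySeries,
    night_index: int = 0,
    offset_min: int = 60,
    **kwargs,
) -> PulseSpec:
    """Pulse starting ``offset_min`` after the given lights-off transition."""
    offs = transition_minutes(series, "lights_off")
    if not 0 <= night_index < len(offs):
        raise IndexError(f"night_index {night_index} out of range (have {len(offs)})")
    return PulseSpec(pulse_start=offs[night_index] + offset_min, **kwargs)


def _check_pulse(series: ActivitySeries, pulse: PulseSpec) -> None:
    if pulse.pulse_start >= len(series):
        raise ValueError("pulse outside recording")
    if pulse.pulse_start + pulse.response_horizon_min > len(series):
        raise ValueError("response horizon extends past the recording")


def eligibility(series: ActivitySeries, pulse: PulseSpec) -> bool:
    """True iff the fly is inside a sleep bout at pulse onset."""
    _check_pulse(series, pulse)
    return bool(sleep_mask(series)[pulse.pulse_start])


def arousal_latency(series: ActivitySeries, pulse: PulseSpec) -> float | None:
    """Minutes from pulse onset to the first minute with any activity.

    None if the fly shows no activity within the response horizon.  The
    scan covers minutes ``pulse_start .. pulse_start + horizon`` inclusive,
    matching the window the non-responder rule checks, so a responder
    always has a defined latency.
    """
    _check_pulse(series, pulse)
    window = series.counts[
        pulse.pulse_start: pulse.pulse_start + pulse.response_horizon_min + 1
    ]
    active = np.flatnonzero(np.nan_to_num(window) > 0)
    return float(active[0]) if active.size else None


def next_day_window(series: ActivitySeries, pulse: PulseSpec) -> tuple[int, int]:
    """The 24 h following the first lights-on after the pulse."""
    ons = [t for t in transition_minutes(series, "lights_on") if t > pulse.pulse_start]
    if not ons:
        raise ValueError("no lights-on transition after the pulse")
    return ons[0], ons[0] + MINUTES_PER_DAY


def classify_nonresponder(series: ActivitySeries, pulse: PulseSpec) -> bool | None:
    """Non-responder: silent for 3 h post-pulse yet active the next day.

    Returns None (censored/excluded) when the recording ends before the
    next-day window or when a death call covers the post-pulse silence —
    the definition exists precisely to exclude dead flies.
    """
    _check_pulse(series, pulse)
    horizon = series.counts[
        pulse.pulse_start + 1: pulse.pulse_start + 1 + pulse.response_horizon_min
    ]
    if np.nan_to_num(horizon).sum() > 0:
        return False
    death = call_death(series)
    if death is not None and death <= pulse.pulse_start + pulse.response_horizon_min:
        return None
    try:
        start, end = next_day_window(series, pulse)
    except ValueError:
        return None
    if end > len(series):
        return None
    if np.nan_to_num(series.counts[start:end]).sum() > 0:
        return True
    # silent post-pulse and silent the next day: cannot be told apart from
    # death even without a formal death call, so exclude
    return None


def assay_cohort(series_list: Sequence[ActivitySeries], pulse: PulseSpec) -> pd.DataFrame:
    """Run the full arousal assay on a cohort; one row per fly."""
    rows = []
    for s in series_list:
        res = ArousalResult(fly_id=s.fly_id, eligible=eligibility(s, pulse))
        if res.eligible:
            res.non_responder = classify_nonresponder(s, pulse)
            if res.non_responder is False:
                res.latency_min = arousal_latency(s, pulse)
            w = s.counts[pulse.pulse_start: pulse.pulse_start + pulse.post_activity_window_min]
            res.post_pulse_activity = float(np.nansum(w))
        rows.append(res.to_dict())
    return pd.DataFrame(rows)


def sleep_in_window(series: ActivitySeries, start: int, end: int) -> float:
    """Minutes asleep within [start, end), scored on the whole series."""
    if not 0 <= start < end <= len(series):
        raise ValueError(f"window [{start}, {end}) outside recording of {len(series)} min")
    return float(sleep_mask(series)[start:end].sum())


def rebound_delta(series: ActivitySeries, deprivation_window: tuple[int, int]) -> float:
    """Post-deprivation sleep gain over the matched window a day earlier.

    (total sleep in the 12 h after deprivation end) minus (total sleep in
    the same clock-time 12 h window 24 h earlier).
    """
    dep_start, dep_end = deprivation_window
    post = (dep_end, dep_end + HALF_DAY)
    pre = (dep_end - MINUTES_PER_DAY, dep_end - MINUTES_PER_DAY + HALF_DAY)
    if pre[0] < 0 or post[1] > len(series):
        raise ValueError("matched pre/post windows do not fit the recording")
    return sleep_in_window(series, *post) - sleep_in_window(series, *pre)


@dataclass(frozen=True)
class Efficacy:
    value: float | None  # fraction of baseline sleep lost, floored at 0
    clipped: bool = False


def deprivation_efficacy(
    series: ActivitySeries, deprivation_window: tuple[int, int]
) -> Efficacy:
    """Fraction of baseline sleep lost during the deprivation window.

    Baseline is the same clock-time window one day earlier.  Reported on
    a 0 floor (a negative loss is clipped and flagged); None if the fly
    had no baseline sleep to lose.
    """
    dep_start, dep_end = deprivation_window
    base = (dep_start - MINUTES_PER_DAY, dep_end - MINUTES_PER_DAY)
    if base[0] < 0:
        raise ValueError("no baseline window before the deprivation window")
    baseline = sleep_in_window(series, *base)
    if baseline == 0:
        return Efficacy(value=None)
    eff = 1.0 - sleep_in_window(series, dep_start, dep_end) / baseline
    if eff < 0:
        return Efficacy(value=0.0, clipped=True)
    return Efficacy(value=eff)
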