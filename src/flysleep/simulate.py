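"""Ground-truthed synthetic data: DAM-style activity and tube-video fixtures.

Activity generator
------------------
Each fly's minute-resolution behavior is a two-state (wake/sleep)
discrete-time Markov chain.  Per-minute hazards are phase-dependent:
``p_ws_day``/``p_ws_night`` (wake->sleep, the circadian modulation of
sleep pressure) and ``p_sw_day``/``p_sw_night`` (sleep->wake, the arousal
hazard; day siesta is shallow with short bouts, night sleep deep with
long bouts).  A single *fragmentation factor* ``k`` scales all four
hazards jointly: the stationary sleep fraction ``p_ws/(p_ws + p_sw)`` is
invariant in ``k`` while bout frequency scales with it, which is exactly
the low-sugar diet phenotype (more sleep bouts, unchanged total sleep and
waking activity).  Waking minutes emit zero-truncated Poisson counts
(``1 + Poisson(lambda_wake - 1)``), so the latent state is exactly
recoverable from the counts; sleeping (and dead) minutes emit zero.

Protocols modify the chain mid-run: a light pulse scales the arousal
hazard by ``1 + multiplier`` during the pulse and the response horizon
(the diet-dependent multiplier encodes arousal threshold); mechanical
deprivation forces sleeping flies awake each minute with high
probability, followed by a transient rebound boost of sleep pressure.

Randomness is organised in per-fly substreams keyed by ``(seed, fly)``:
re-running with the same seed is byte-identical, and two runs differing
only in parameters share their underlying random numbers (common random
numbers — the standard variance-reduction design when comparing
simulator configurations such as the k=1 vs k=2 diet contrast).

Trajectory generator
--------------------
A semi-Markov process over {move, pause, feed, sleep} produces 1 Hz
positions of a fly confined to a 1-D tube with food at one end: movement
is a correlated random walk with reflecting ends, feeding requires
visiting the food zone, and sleep stops occur away from the food with a
dwell of at least the video sleep threshold.  ``render_frames`` draws the
trajectory as a dark elliptical blob on a light tube background with
additive Gaussian noise, yielding frame stacks with exact ground truth
for the tracking pipeline.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from datetime import date, datetime, time
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .dam import HALF_DAY, MINUTES_PER_DAY, ActivitySeries, write_dam
from .video import TubeROI

WAKE, SLEEP, DEAD = 0, 1, 2


@dataclass(frozen=True)
class PulseProtocol:
    """A wake-inducing light pulse delivered after lights-off."""

    night_index: int = 0
    offset_min: int = 60  # minutes after lights-off
    duration_min: int = 5
    multiplier: float = 0.0  # arousal-hazard scaling is (1 + multiplier)
    horizon_min: int = 180  # multiplier also applies through the response horizon

    def __post_init__(self) -> None:
        if self.multiplier < 0:
            raise ValueError("multiplier must be >= 0")


@dataclass(frozen=True)
class DeprivationProtocol:
    """One night of mechanical sleep deprivation plus homeostatic rebound."""

    night_index: int = 3
    forced_wake_p: float = 0.98  # per-minute probability a sleeping fly is shaken awake
    rebound_boost: float = 1.5  # multiplier on p_ws after the window
    rebound_min: int = 720

    def __post_init__(self) -> None:
        if not 0 <= self.forced_wake_p <= 1:
            raise ValueError("forced_wake_p must be a probability")
        if self.rebound_boost <= 0:
            raise ValueError("rebound_boost must be positive")


@dataclass(frozen=True)
class SimParams:
    """Full parameterization of the activity generator.

    Hazard defaults give ~44% day sleep in ~20-min bouts, ~90% night
    sleep in ~2-h bouts and roughly a dozen scored sleep bouts per day at
    k=1 — a realistic male-fly architecture under 12:12 LD.
    """

    n_flies: int = 16
    days: int = 6
    seed: int = 0
    p_ws_day: float = 0.02
    p_ws_night: float = 0.072
    p_sw_day: float = 0.025
    p_sw_night: float = 0.008
    fragmentation_k: float = 1.0
    lambda_wake: float = 2.0
    zero_truncated: bool = True
    regime: str = "LD12:12"
    lights_on: time = time(8, 0)
    start_date: date = date(2012, 1, 2)
    fly_prefix: str = "fly"
    pulse: PulseProtocol | None = None
    deprivation: DeprivationProtocol | None = None
    death_times: tuple | None = None  # optional per-fly death minute

    def __post_init__(self) -> None:
        k = self.fragmentation_k
        if k <= 0:
            raise ValueError("fragmentation_k must be positive")
        for name in ("p_ws_day", "p_ws_night", "p_sw_day", "p_sw_night"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be a probability")
            if k * p > 1:
                raise ValueError(f"fragmentation_k * {name} exceeds 1")
        if self.pulse is not None and k * self.p_sw_night * (1 + self.pulse.multiplier) > 1:
            raise ValueError("pulse multiplier drives the arousal hazard above 1")
        if self.lambda_wake <= (1.0 if self.zero_truncated else 0.0):
            raise ValueError("lambda_wake too small for the count model")
        if self.n_flies < 1 or self.days < 1:
            raise ValueError("n_flies and days must be >= 1")
        if self.death_times is not None and len(self.death_times) != self.n_flies:
            raise ValueError("death_times must have one entry per fly")

    @property
    def minutes(self) -> int:
        return self.days * MINUTES_PER_DAY

    @property
    def start_time(self) -> datetime:
        return datetime.combine(self.start_date, self.lights_on)

    def manifest(self) -> dict:
        d = asdict(self)
        d["lights_on"] = self.lights_on.isoformat()
        d["start_date"] = self.start_date.isoformat()
        return d


@dataclass
class SimResult:
    """Simulated cohort plus its per-minute latent ground truth."""

    params: SimParams
    series: list[ActivitySeries]
    states: np.ndarray  # (n_flies, T) with WAKE/SLEEP/DEAD codes

    @property
    def fly_ids(self) -> list[str]:
        return [s.fly_id for s in self.series]

    def true_sleep_minutes(self, fly: int) -> int:
        return int((self.states[fly] == SLEEP).sum())

    def true_bouts(self, fly: int) -> list[tuple[int, int]]:
        """Maximal latent sleep runs as half-open (start, end) intervals."""
        asleep = np.concatenate(([False], self.states[fly] == SLEEP, [False]))
        starts = np.flatnonzero(~asleep[:-1] & asleep[1:])
        ends = np.flatnonzero(asleep[:-1] & ~asleep[1:])
        return list(zip(starts.tolist(), ends.tolist()))

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for i, fid in enumerate(self.fly_ids):
            bouts = self.true_bouts(i)
            rows.append(
                {"fly_id": fid,
                 "true_sleep_min": self.true_sleep_minutes(i),
                 "true_bout_count": len(bouts),
                 "true_bouts_ge5": sum(e - s >= 5 for s, e in bouts)}
            )
        return pd.DataFrame(rows)


def _light_day_mask(params: SimParams, T: int | None = None) -> np.ndarray:
    template = ActivitySeries(
        fly_id="_template",
        start_time=params.start_time,
        counts=np.zeros(T if T is not None else params.minutes),
        regime=params.regime,
        lights_on=params.lights_on,
    )
    return template.light_state


def minute_hazards(params: SimParams, T: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-minute k-scaled hazards (p_ws[t], p_sw[t]) over the recording."""
    day = _light_day_mask(params, T)
    k = params.fragmentation_k
    p_ws = np.where(day, params.p_ws_day, params.p_ws_night) * k
    p_sw = np.where(day, params.p_sw_day, params.p_sw_night) * k
    return p_ws, p_sw


def _protocol_windows(params: SimParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-minute multipliers/forcing implied by the configured protocols.

    Returns (p_sw multiplier, p_ws multiplier, forced-wake probability).
    """
    T = params.minutes
    sw_mult = np.ones(T)
    ws_mult = np.ones(T)
    forced = np.zeros(T)
    if params.pulse is not None:
        p = params.pulse
        # nights start at ZT12 of each day: minute 720, 2160, ...
        start = p.night_index * MINUTES_PER_DAY + HALF_DAY + p.offset_min
        end = start + p.duration_min + p.horizon_min
        if start >= T:
            raise ValueError("pulse outside recording")
        sw_mult[start:min(end, T)] = 1 + p.multiplier
    if params.deprivation is not None:
        d = params.deprivation
        w0 = d.night_index * MINUTES_PER_DAY + HALF_DAY
        w1 = w0 + HALF_DAY
        if w1 > T:
            raise ValueError("deprivation window outside recording")
        forced[w0:w1] = d.forced_wake_p
        ws_mult[w1:min(w1 + d.rebound_min, T)] = d.rebound_boost
    return sw_mult, ws_mult, forced


def deprivation_window(params: SimParams) -> tuple[int, int]:
    """The configured deprivation window as minute indices (start, end)."""
    if params.deprivation is None:
        raise ValueError("no deprivation protocol configured")
    w0 = params.deprivation.night_index * MINUTES_PER_DAY + HALF_DAY
    return w0, w0 + HALF_DAY


def pulse_start_minute(params: SimParams) -> int:
    if params.pulse is None:
        raise ValueError("no pulse protocol configured")
    return params.pulse.night_index * MINUTES_PER_DAY + HALF_DAY + params.pulse.offset_min


def simulate_activity(params: SimParams) -> SimResult:
    """Run the two-state generator for a cohort of flies.

    Returns per-fly :class:`ActivitySeries` (the observable) and the
    latent state matrix (the ground truth).  Determinism: identical
    params (including seed) give identical output; flies occupy
    independent RNG substreams keyed by (seed, fly index).
    """
    T = params.minutes
    n = params.n_flies
    p_ws, p_sw = minute_hazards(params)
    sw_mult, ws_mult, forced = _protocol_windows(params)
    p_sw_eff = np.clip(p_sw * sw_mult, 0, 1)
    p_ws_eff = np.clip(p_ws * ws_mult, 0, 1)

    # Separate uniform streams for the two transition types realize the
    # common-random-numbers coupling: two runs differing only in hazards
    # share every threshold comparison, so their sample paths correlate.
    u_init = np.empty(n)
    u_fall = np.empty((n, T))
    u_wake = np.empty((n, T))
    u_force = np.empty((n, T))
    counts_wake = np.empty((n, T), dtype=np.int64)
    for i in range(n):
        rng = np.random.default_rng([params.seed, i])
        u_init[i] = rng.random()
        u_fall[i] = rng.random(T)
        u_wake[i] = rng.random(T)
        u_force[i] = rng.random(T)
        if params.zero_truncated:
            counts_wake[i] = 1 + rng.poisson(params.lambda_wake - 1, T)
        else:
            counts_wake[i] = rng.poisson(params.lambda_wake, T)

    states = np.empty((n, T), dtype=np.uint8)
    pi_s0 = p_ws[0] / (p_ws[0] + p_sw[0]) if p_ws[0] + p_sw[0] > 0 else 0.0
    asleep = u_init < pi_s0
    if forced[0] > 0:
        asleep &= ~(u_force[:, 0] < forced[0])
    states[:, 0] = np.where(asleep, SLEEP, WAKE)
    for t in range(1, T):
        stay = u_wake[:, t] >= p_sw_eff[t]
        fall = u_fall[:, t] < p_ws_eff[t]
        asleep = np.where(asleep, stay, fall)
        if forced[t] > 0:
            asleep &= ~(u_force[:, t] < forced[t])
        states[:, t] = np.where(asleep, SLEEP, WAKE)

    if params.death_times is not None:
        for i, dt in enumerate(params.death_times):
            if dt is not None and dt < T:
                states[i, dt:] = DEAD

    counts = np.where(states == WAKE, counts_wake, 0)
    series = [
        ActivitySeries(
            fly_id=f"{params.fly_prefix}{i:02d}",
            start_time=params.start_time,
            counts=counts[i].astype(float),
            regime=params.regime,
            lights_on=params.lights_on,
        )
        for i in range(n)
    ]
    return SimResult(params=params, series=series, states=states)


def apply_pulse_protocol(result: SimResult, pulse: PulseProtocol) -> SimResult:
    """Re-run the generator with a light pulse added.

    Shared RNG substreams make the modified run identical to the input up
    to the pulse onset.
    """
    return simulate_activity(replace(result.params, pulse=pulse))


def apply_deprivation_protocol(result: SimResult, deprivation: DeprivationProtocol) -> SimResult:
    """Re-run the generator with a deprivation night added (see above)."""
    return simulate_activity(replace(result.params, deprivation=deprivation))


def stationary_sleep_fraction(params: SimParams, phase: str = "night") -> float:
    """Within-phase stationary sleep fraction p_ws/(p_ws+p_sw); k-invariant."""
    p_ws = params.p_ws_day if phase == "day" else params.p_ws_night
    p_sw = params.p_sw_day if phase == "day" else params.p_sw_night
    return p_ws / (p_ws + p_sw)


def periodic_sleep_marginal(params: SimParams, n_cycles: int = 30) -> np.ndarray:
    """Exact per-minute P(asleep) over the circadian day at periodic steady state."""
    p_ws, p_sw = minute_hazards(params, T=MINUTES_PER_DAY)
    pi = np.empty(MINUTES_PER_DAY)
    p = p_ws[0] / (p_ws[0] + p_sw[0])
    for _ in range(n_cycles):
        for t in range(MINUTES_PER_DAY):
            p = p * (1 - p_sw[t]) + (1 - p) * p_ws[t]
            pi[t] = p
    return pi


def expected_sleep_bouts_per_day(params: SimParams) -> float:
    """Expected scored sleep bouts (zero runs >= 5 min) per day.

    A scored bout starts at minute t when an awake fly falls asleep and
    the run survives four further minutes; summing the per-minute start
    rate times the survival product over the periodic steady state gives
    the exact daily rate.  With phase-constant hazards this reduces to
    the closed form ``1440 * pi_w * k*p_ws * (1 - k*p_sw)**4``.
    """
    p_ws, p_sw = minute_hazards(params, T=MINUTES_PER_DAY)
    pi = periodic_sleep_marginal(params)
    total = 0.0
    for t in range(MINUTES_PER_DAY):
        start_rate = (1 - pi[t - 1]) * p_ws[t]
        survive = np.prod(1 - p_sw[(t + 1 + np.arange(4)) % MINUTES_PER_DAY])
        total += start_rate * survive
    return float(total)


def expected_waking_activity(params: SimParams) -> float:
    """Expected beam crosses per non-sleep-bout minute (zero-truncated model)."""
    return params.lambda_wake


def emit_experiment(
    groups: Mapping[str, SimResult],
    outdir,
    monitor_prefix: str = "monitor",
) -> dict:
    """Write simulated groups as monitor files, design CSV, truth and manifest.

    Each group becomes one monitor file (channels 1..n); the design table
    assigns diet = group name, with the last-listed group flagged as the
    control unless a group is literally named 'HS' (the high-sugar
    reference diet), which is then the control.  Returns the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = list(groups)
    control = "HS" if "HS" in names else names[-1]
    design_rows = []
    truths = []
    manifest: dict = {"groups": {}, "control": control}
    for gi, (name, result) in enumerate(groups.items()):
        monitor_id = f"{monitor_prefix}{gi + 1}"
        path = outdir / f"{monitor_id}.txt"
        write_dam({ch + 1: s for ch, s in enumerate(result.series)}, path)
        for ch, s in enumerate(result.series):
            design_rows.append(
                {"monitor_id": monitor_id, "channel": ch + 1, "fly_id": s.fly_id,
                 "genotype": "sim", "diet": name, "sex": "M", "cohort": "c1",
                 "is_control": name == control, "regime": result.params.regime}
            )
        t = result.truth_frame()
        t.insert(1, "diet", name)
        truths.append(t)
        manifest["groups"][name] = result.params.manifest()
    pd.DataFrame(design_rows).to_csv(outdir / "design.csv", index=False)
    pd.concat(truths, ignore_index=True).to_csv(outdir / "ground_truth.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


# ---------------------------------------------------------------------------
# Tube trajectory simulation and rendering
# ---------------------------------------------------------------------------

MOVE, PAUSE, FEED, TSLEEP = 0, 1, 2, 3
STATE_NAMES = {MOVE: "move", PAUSE: "pause", FEED: "feed", TSLEEP: "sleep"}


@dataclass(frozen=True)
class TrajectoryParams:
    """Kinematics and behavioral rates of the tube trajectory generator."""

    duration_s: int = 3600
    fps: float = 1.0
    tube_length_mm: float = 65.0
    tube_width_mm: float = 5.0
    body_length_mm: float = 2.5
    speed_mm_s: float = 2.5
    dir_flip_p: float = 0.05  # per-second heading reversal while moving
    mean_move_s: float = 25.0
    p_feed: float = 0.25  # stop-type probabilities at the end of a move episode
    p_sleep: float = 0.12
    feed_mean_s: float = 90.0
    sleep_min_s: float = 330.0
    sleep_extra_mean_s: float = 600.0
    pause_mean_s: float = 20.0
    pause_max_s: float = 200.0  # pauses never reach the video sleep threshold
    post_sleep_feed_p: float = 0.0  # P(go straight to the food after a sleep stop)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_feed + self.p_sleep > 1:
            raise ValueError("p_feed + p_sleep must be <= 1")
        if self.sleep_min_s <= self.pause_max_s:
            raise ValueError("sleep_min_s must exceed pause_max_s")


@dataclass
class Trajectory:
    """1 Hz positions (mm, food at x=0) with per-second state labels."""

    params: TrajectoryParams
    x_mm: np.ndarray
    y_mm: np.ndarray
    states: np.ndarray

    def __len__(self) -> int:
        return self.x_mm.size

    def sleep_intervals(self, min_duration_s: float = 300.0) -> list[tuple[int, int]]:
        """Ground-truth immobility runs >= the threshold (half-open seconds)."""
        still = np.concatenate(([False], np.isin(self.states, (TSLEEP,)), [False]))
        starts = np.flatnonzero(~still[:-1] & still[1:])
        ends = np.flatnonzero(still[:-1] & ~still[1:])
        return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_duration_s]


def simulate_trajectory(tp: TrajectoryParams) -> Trajectory:
    """Generate one fly's tube trajectory (semi-Markov over move/pause/feed/sleep)."""
    rng = np.random.default_rng([tp.seed, 97])
    T = tp.duration_s
    L = tp.tube_length_mm
    bl = tp.body_length_mm
    x = np.empty(T)
    y = np.empty(T)
    states = np.empty(T, dtype=np.uint8)
    pos = L / 2
    direction = 1.0 if rng.random() < 0.5 else -1.0
    y_center = tp.tube_width_mm / 2
    t = 0

    def walk_step() -> None:
        nonlocal pos, direction
        if rng.random() < tp.dir_flip_p:
            direction = -direction
        pos += direction * tp.speed_mm_s
        lo, hi = 0.3, L - 0.3
        if pos < lo:
            pos, direction = lo + (lo - pos), 1.0
        elif pos > hi:
            pos, direction = hi - (pos - hi), -1.0

    def emit(state: int) -> bool:
        nonlocal t
        if t >= T:
            return False
        x[t] = pos
        y[t] = y_center + (rng.normal(0, 0.15) if state == MOVE else 0.0)
        states[t] = state
        t += 1
        return True

    def walk_to(target: float) -> None:
        nonlocal pos, direction
        while t < T and abs(pos - target) > tp.speed_mm_s:
            direction = 1.0 if target > pos else -1.0
            pos += direction * tp.speed_mm_s
            if not emit(MOVE):
                return
        pos = target

    def dwell(state: int, seconds: int) -> None:
        for _ in range(seconds):
            if not emit(state):
                return

    def feed_visit() -> None:
        walk_to(bl * 0.4)
        dwell(FEED, max(1, int(round(rng.exponential(tp.feed_mean_s)))))

    while t < T:
        for _ in range(max(1, int(round(rng.exponential(tp.mean_move_s))))):
            walk_step()
            if not emit(MOVE):
                break
        if t >= T:
            break
        r = rng.random()
        if r < tp.p_feed:
            feed_visit()
        elif r < tp.p_feed + tp.p_sleep:
            # sleep happens away from the food; approach in full-speed steps so
            # the displacement into/out of a sleep stop is never near-threshold
            while t < T and pos < 3 * bl:
                pos = min(pos + tp.speed_mm_s, L - 0.3)
                if not emit(MOVE):
                    break
            dwell(
                TSLEEP,
                int(round(tp.sleep_min_s + rng.exponential(tp.sleep_extra_mean_s))),
            )
            if t < T and rng.random() < tp.post_sleep_feed_p:
                feed_visit()
        else:
            dwell(
                PAUSE,
                max(1, int(round(min(rng.exponential(tp.pause_mean_s), tp.pause_max_s)))),
            )
    return Trajectory(params=tp, x_mm=x, y_mm=y, states=states)


@dataclass(frozen=True)
class RenderParams:
    """Camera model for rendering trajectories to grayscale frames."""

    pixels_per_mm: float = 4.0
    margin_px: int = 6
    background_level: float = 200.0
    fly_amplitude: float = 120.0  # peak darkening under the fly
    fly_sigma_mm: tuple[float, float] = (0.6, 0.35)  # along-tube, across-tube
    noise_sd: float = 3.0
    seed: int = 0


def render_frames(
    traj: Trajectory, rp: RenderParams = RenderParams()
) -> tuple[np.ndarray, TubeROI]:
    """Render a trajectory to a uint8 frame stack plus its tube ROI.

    The fly is a dark elliptical (Gaussian-profile) blob on a flat light
    background with additive Gaussian pixel noise.  Ground truth stays on
    the trajectory object.
    """
    tp = traj.params
    ppm = rp.pixels_per_mm
    m = rp.margin_px
    w_tube = int(math.ceil(tp.tube_length_mm * ppm))
    h_tube = int(math.ceil(tp.tube_width_mm * ppm))
    W, H = w_tube + 2 * m, h_tube + 2 * m
    if (traj.x_mm < 0).any() or (traj.x_mm > tp.tube_length_mm).any():
        raise ValueError("trajectory leaves the tube")
    rng = np.random.default_rng([rp.seed, 211])
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    base = np.full((H, W), rp.background_level)
    base[m - 1, :] = base[m + h_tube, :] = rp.background_level * 0.75  # tube walls
    sx = rp.fly_sigma_mm[0] * ppm
    sy = rp.fly_sigma_mm[1] * ppm
    frames = np.empty((len(traj), H, W), dtype=np.uint8)
    for i in range(len(traj)):
        cx = m + traj.x_mm[i] * ppm
        cy = m + traj.y_mm[i] * ppm
        blob = rp.fly_amplitude * np.exp(
            -(((xx - cx) ** 2) / (2 * sx**2) + ((yy - cy) ** 2) / (2 * sy**2))
        )
        img = base - blob
        if rp.noise_sd > 0:
            img = img + rng.normal(0, rp.noise_sd, size=img.shape)
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)
    roi = TubeROI(
        fly_id="tube00",
        x0=m, y0=m, x1=m + w_tube, y1=m + h_tube,
        food_end="left",
        pixels_per_mm=ppm,
        body_length_px=tp.body_length_mm * ppm,
    )
    return frames, roi


def true_track(traj: Trajectory, roi: TubeROI, rp: RenderParams = RenderParams()):
    """The trajectory expressed in pixel coordinates (tracking ground truth)."""
    from .video import Track

    return Track(
        fly_id=roi.fly_id,
        x=rp.margin_px + traj.x_mm * rp.pixels_per_mm,
        y=rp.margin_px + traj.y_mm * rp.pixels_per_mm,
        detected=np.ones(len(traj), bool),
        roi=roi,
        fps=traj.params.fps,
    )
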