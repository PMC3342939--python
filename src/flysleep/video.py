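"""Centroid tracking and behavioral scoring for tube-array video.

Single flies are housed in horizontal tubes with food at one end and a
cotton plug at the other, filmed from above at 1 frame/s.  Tracking is
background-composite subtraction: the per-pixel median over sampled
frames rejects the moving fly and leaves the empty tube; each frame's
absolute difference from that composite is thresholded inside the tube
ROI and the intensity-weighted centroid of the largest connected
component is the fly position.

Behavioral definitions on the resulting track:

* video sleep — every consecutive-frame centroid displacement below 2 px
  for at least 5 minutes (per-frame movement, not net displacement);
* feeding bout — a maximal period with the centroid within one body
  length of the food end, measured along the tube axis;
* distance travelled — summed consecutive-frame Euclidean displacement.

All pixel geometry is 0-based with the origin at the top-left corner.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import measure

@dataclass(frozen=True)
class TubeROI:
    """A tube's rectangle [x0, x1) x [y0, y1) in pixels, plus geometry.

    ``food_end`` says which short edge of the rectangle holds the food
    ("left" or "right"); axial positions are measured from that edge
    toward the plug.
    """

    fly_id: str
    x0: int
    y0: int
    x1: int
    y1: int
    food_end: str = "left"
    pixels_per_mm: float = 4.0
    body_length_px: float = 10.0  # 2.5 mm at the default scale

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError("ROI rectangle is empty")
        if self.food_end not in ("left", "right"):
            raise ValueError("food_end must be 'left' or 'right'")
        if self.pixels_per_mm <= 0 or self.body_length_px <= 0:
            raise ValueError("pixels_per_mm and body_length_px must be positive")

    def axial_position_px(self, x: np.ndarray) -> np.ndarray:
        """Distance (px) from the food end along the tube axis."""
        x = np.asarray(x, float)
        return x - self.x0 if self.food_end == "left" else (self.x1 - 1) - x


@dataclass
class Track:
    """Per-frame centroid positions for one fly inside a tube ROI."""

    fly_id: str
    x: np.ndarray
    y: np.ndarray
    detected: np.ndarray
    roi: TubeROI
    fps: float = 1.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.detected = np.asarray(self.detected, bool)
        if not (self.x.size == self.y.size == self.detected.size):
            raise ValueError("x, y and detected must have equal length")

    def __len__(self) -> int:
        return self.x.size

    @property
    def axial_position_px(self) -> np.ndarray:
        return self.roi.axial_position_px(self.x)

    @property
    def axial_position_mm(self) -> np.ndarray:
        return self.axial_position_px / self.roi.pixels_per_mm

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": np.arange(len(self)), "x": self.x, "y": self.y,
             "detected": self.detected}
        )


def load_frames(path) -> np.ndarray:
    """Load a frame stack from a multi-page TIFF or a directory of images."""
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not files:
            raise FileNotFoundError(f"no frames in {path}")
        return np.stack([iio.imread(p) for p in files])
    import tifffile

    return tifffile.imread(path)


def build_background(frames: np.ndarray, sample_stride: int = 1) -> np.ndarray:
    """Background composite: per-pixel median over sampled frames.

    The median rejects the fly wherever it occupies a pixel in fewer than
    half of the sampled frames.
    """
    if sample_stride < 1:
        raise ValueError("sample_stride must be >= 1")
    sampled = frames[::sample_stride]
    if sampled.shape[0] < 30:
        raise ValueError(
            f"need >= 30 sampled frames for a stable background, got {sampled.shape[0]}"
        )
    return np.median(sampled.astype(float), axis=0)


def detect_fly(
    frame: np.ndarray,
    background: np.ndarray,
    roi: TubeROI,
    threshold: float,
    min_area: int = 4,
) -> tuple[tuple[float, float] | None, bool]:
    """Locate the fly in one frame as an intensity-weighted centroid.

    The absolute difference from the background composite is thresholded
    inside the ROI; the centroid of the largest connected component is
    returned in full-frame coordinates, or ``(None, False)`` if no
    component reaches ``min_area``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    h, w = frame.shape
    if roi.x1 > w or roi.y1 > h or roi.x0 < 0 or roi.y0 < 0:
        raise ValueError("ROI outside frame bounds")
    diff = np.abs(
        frame[roi.y0:roi.y1, roi.x0:roi.x1].astype(float)
        - background[roi.y0:roi.y1, roi.x0:roi.x1]
    )
    mask = diff > threshold
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return None, False
    areas = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(areas)) + 1
    if areas[best - 1] < min_area:
        return None, False
    sel = labels == best
    weights = diff * sel
    total = weights.sum()
    ys, xs = np.mgrid[0: roi.y1 - roi.y0, 0: roi.x1 - roi.x0]
    cy = (weights * ys).sum() / total + roi.y0
    cx = (weights * xs).sum() / total + roi.x0
    return (float(cx), float(cy)), True


def track(
    frames: np.ndarray,
    rois: Sequence[TubeROI],
    threshold: float,
    min_area: int = 4,
    background: np.ndarray | None = None,
    sample_stride: int = 1,
    qc_tolerance: float = 0.01,
    fps: float = 1.0,
) -> tuple[list[Track], pd.DataFrame]:
    """Track one fly per ROI across a frame stack, with a QC report.

    Missed detections carry the last known position forward and are
    flagged; a fly whose missing fraction exceeds ``qc_tolerance`` fails
    QC in the report (``qc_pass`` False).
    """
    if background is None:
        background = build_background(frames, sample_stride)
    tracks: list[Track] = []
    qc_rows = []
    n = frames.shape[0]
    for roi in rois:
        xs = np.empty(n)
        ys = np.empty(n)
        det = np.zeros(n, dtype=bool)
        last = (roi.x0 + (roi.x1 - roi.x0) / 2, roi.y0 + (roi.y1 - roi.y0) / 2)
        for i in range(n):
            pos, ok = detect_fly(frames[i], background, roi, threshold, min_area)
            if ok:
                last = pos
            xs[i], ys[i] = last
            det[i] = ok
        missing = 1.0 - det.mean() if n else 1.0
        qc_rows.append(
            {"fly_id": roi.fly_id, "n_frames": n,
             "n_missing": int(n - det.sum()),
             "missing_frac": missing, "qc_pass": missing <= qc_tolerance}
        )
        tracks.append(Track(fly_id=roi.fly_id, x=xs, y=ys, detected=det, roi=roi, fps=fps))
    return tracks, pd.DataFrame(qc_rows)


def displacement_series(trk: Track) -> np.ndarray:
    """Euclidean centroid displacement (px) per consecutive frame pair."""
    if len(trk) < 2:
        raise ValueError("need at least 2 frames")
    return np.hypot(np.diff(trk.x), np.diff(trk.y))


def distance_per_hour(trk: Track) -> np.ndarray:
    """Total distance (mm) travelled in each full hour of the track."""
    d_mm = displacement_series(trk) / trk.roi.pixels_per_mm
    per_hour = int(round(3600 * trk.fps))
    n_hours = d_mm.size // per_hour
    if n_hours == 0:
        return np.array([d_mm.sum()])
    tail = d_mm[: n_hours * per_hour]
    return tail.reshape(n_hours, per_hour).sum(axis=1)


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean vector as half-open (start, end)."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    return list(zip(starts.tolist(), ends.tolist()))


def video_sleep(
    trk: Track, px_threshold: float = 2.0, min_duration_s: float = 300.0
) -> list[tuple[int, int]]:
    """Sleep intervals: sustained sub-threshold per-frame movement.

    An interval is a maximal frame span [start, end) in which *every*
    consecutive-frame displacement is below ``px_threshold``; it counts
    as sleep if its duration (number of displacements / fps) reaches
    ``min_duration_s``.
    """
    small = displacement_series(trk) < px_threshold
    min_steps = int(np.ceil(min_duration_s * trk.fps))
    return [(s, e + 1) for s, e in _runs_of(small) if e - s >= min_steps]


@dataclass
class FeedingSummary:
    bouts: list[tuple[int, int]]
    mean_trip_duration_s: float
    fraction_over_5min: float


def feeding_bouts(trk: Track, over_threshold_s: float = 300.0) -> FeedingSummary:
    """Feeding bouts: maximal periods within one body length of the food."""
    near = trk.axial_position_px <= trk.roi.body_length_px
    bouts = _runs_of(near)
    durations = np.array([(e - s) / trk.fps for s, e in bouts])
    return FeedingSummary(
        bouts=bouts,
        mean_trip_duration_s=float(durations.mean()) if durations.size else np.nan,
        fraction_over_5min=float((durations > over_threshold_s).mean())
        if durations.size
        else np.nan,
    )


def post_sleep_food_approach(
    sleep_intervals: Sequence[tuple[int, int]],
    feeding: FeedingSummary | Sequence[tuple[int, int]],
    window_s: float = 120.0,
    fps: float = 1.0,
) -> float | None:
    """Fraction of sleep bouts followed by a food-zone entry within the window."""
    bouts = feeding.bouts if isinstance(feeding, FeedingSummary) else list(feeding)
    if not sleep_intervals:
        return None
    window_frames = window_s * fps
    starts = np.array([s for s, _ in bouts])
    hits = 0
    for _, sleep_end in sleep_intervals:
        if starts.size and np.any((starts >= sleep_end) & (starts <= sleep_end + window_frames)):
            hits += 1
    return hits / len(sleep_intervals)


ROI_COLUMNS = ["fly_id", "x0", "y0", "x1", "y1", "food_end", "pixels_per_mm", "body_length_px"]


def read_rois(path) -> list[TubeROI]:
    rois = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rois.append(
                TubeROI(
                    fly_id=row["fly_id"],
                    x0=int(row["x0"]), y0=int(row["y0"]),
                    x1=int(row["x1"]), y1=int(row["y1"]),
                    food_end=row["food_end"],
                    pixels_per_mm=float(row["pixels_per_mm"]),
                    body_length_px=float(row["body_length_px"]),
                )
            )
    return rois


def write_rois(rois: Sequence[TubeROI], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=ROI_COLUMNS)
        writer.writeheader()
        for r in rois:
            writer.writerow({c: getattr(r, c) for c in ROI_COLUMNS})
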