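"""Locomotion and rest metrics: distance traveled, immobility-bout
detection, and the zone distribution of resting time.

Distance accumulates frame-to-frame displacement and therefore inflates
with tracking jitter; positions are median-smoothed (window 5 frames by
default) before both distance and speed computations.  An immobility
("resting") bout is a maximal run of frames with smoothed speed below a
threshold lasting strictly more than ``min_bout_s`` (default 3 s); a single
supra-threshold frame inside a run does not split it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .arena import ArenaGeometry, zone_of_position
from .errors import DegenerateDataError
from .tracks import AnimalTrack

__all__ = [
    "ImmobilityBout",
    "ActivitySummary",
    "distance_traveled",
    "detect_immobility_bouts",
    "resting_summary",
    "activity_frame",
    "bouts_frame",
]

DEFAULT_SPEED_THRESHOLD_CM_S = 0.5
DEFAULT_MIN_BOUT_S = 3.0
DEFAULT_SMOOTH_WINDOW = 5


@dataclass(frozen=True)
class ImmobilityBout:
    start_s: float
    duration_s: float
    zone: int


@dataclass(frozen=True)
class ActivitySummary:
    animal_id: str
    distance_m: float
    resting_percent: float
    bouts: tuple[ImmobilityBout, ...]
    resting_percent_by_zone: np.ndarray


def _window_mask(track: AnimalTrack, window: tuple[float, float] | None):
    if window is None:
        return np.ones(track.n_samples, dtype=bool)
    start, end = window
    return (track.time_s >= start) & (track.time_s < end)


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window and window > 1 and len(x) > window:
        # edge replication avoids the spurious end displacements that
        # zero-padded median filters introduce
        return median_filter(x, size=window, mode="nearest")
    return x


def distance_traveled(
    track: AnimalTrack,
    window: tuple[float, float] | None = None,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> float:
    """Total path length in meters over the window (x only unless the track
    carries a transverse coordinate)."""
    mask = _window_mask(track, window)
    if mask.sum() < 2:
        raise DegenerateDataError("distance needs at least 2 frames in window")
    x = _smooth(track.x_cm[mask], smooth_window)
    dx = np.diff(x)
    if track.y_cm is not None:
        dy = np.diff(_smooth(track.y_cm[mask], smooth_window))
        steps = np.hypot(dx, dy)
    else:
        steps = np.abs(dx)
    return float(steps.sum()) / 100.0


def _frame_speeds(track: AnimalTrack, smooth_window: int) -> np.ndarray:
    """Per-frame speed (cm/s) from smoothed positions; frame 0 inherits
    the first displacement."""
    x = _smooth(track.x_cm, smooth_window)
    if track.y_cm is not None:
        y = _smooth(track.y_cm, smooth_window)
        step = np.hypot(np.diff(x), np.diff(y))
    else:
        step = np.abs(np.diff(x))
    speed = step * track.fps
    return np.concatenate([[speed[0] if len(speed) else 0.0], speed])


def detect_immobility_bouts(
    track: AnimalTrack,
    speed_threshold_cm_s: float = DEFAULT_SPEED_THRESHOLD_CM_S,
    min_bout_s: float = DEFAULT_MIN_BOUT_S,
    arena: ArenaGeometry = ArenaGeometry(),
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    gap_tolerance_frames: int = 1,
) -> list[ImmobilityBout]:
    """Maximal sub-threshold-speed runs lasting strictly more than
    ``min_bout_s``, with up to ``gap_tolerance_frames`` spurious moving
    frames bridged inside a run."""
    if speed_threshold_cm_s <= 0:
        raise ValueError("speed threshold must be positive")
    if track.n_samples < 2:
        return []
    below = _frame_speeds(track, smooth_window) < speed_threshold_cm_s

    if gap_tolerance_frames > 0 and below.any():
        # bridge short gaps: a moving run of <= tol frames flanked by
        # resting frames is absorbed into the surrounding bout
        b = below.copy()
        idx = np.flatnonzero(~b)
        if len(idx):
            splits = np.flatnonzero(np.diff(idx) > 1)
            runs = np.split(idx, splits + 1)
            for run in runs:
                if (
                    len(run) <= gap_tolerance_frames
                    and run[0] > 0
                    and run[-1] < len(b) - 1
                ):
                    b[run] = True
        below = b

    bouts: list[ImmobilityBout] = []
    idx = np.flatnonzero(below)
    if not len(idx):
        return bouts
    splits = np.flatnonzero(np.diff(idx) > 1)
    for run in np.split(idx, splits + 1):
        duration = len(run) / track.fps
        if duration > min_bout_s:
            mean_x = float(track.x_cm[run].mean())
            bouts.append(
                ImmobilityBout(
                    start_s=float(track.time_s[run[0]]),
                    duration_s=duration,
                    zone=zone_of_position(mean_x, arena),
                )
            )
    return bouts


def resting_summary(
    track: AnimalTrack,
    bouts: Sequence[ImmobilityBout],
    arena: ArenaGeometry = ArenaGeometry(),
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> ActivitySummary:
    """Aggregate resting percentage, its per-zone decomposition, and the
    distance traveled."""
    n = track.n_samples
    in_bout = np.zeros(n, dtype=bool)
    for b in bouts:
        i0 = int(np.searchsorted(track.time_s, b.start_s))
        i1 = i0 + int(round(b.duration_s * track.fps))
        in_bout[i0:i1] = True
    resting_percent = 100.0 * in_bout.sum() / n if n else 0.0
    per_zone = np.zeros(arena.n_zones)
    if in_bout.any():
        zones = zone_of_position(track.x_cm[in_bout], arena)
        counts = np.bincount(zones, minlength=arena.n_zones + 1)[1:]
        per_zone = 100.0 * counts / n
    return ActivitySummary(
        animal_id=track.animal_id,
        distance_m=distance_traveled(track, smooth_window=smooth_window)
        if n >= 2
        else 0.0,
        resting_percent=float(resting_percent),
        bouts=tuple(bouts),
        resting_percent_by_zone=per_zone,
    )


def activity_frame(summaries: Sequence[ActivitySummary]) -> pd.DataFrame:
    """Per-animal activity table."""
    return pd.DataFrame(
        {
            "animal_id": [s.animal_id for s in summaries],
            "distance_m": [s.distance_m for s in summaries],
            "resting_percent": [s.resting_percent for s in summaries],
            "n_bouts": [len(s.bouts) for s in summaries],
            "mean_bout_s": [
                float(np.mean([b.duration_s for b in s.bouts])) if s.bouts else 0.0
                for s in summaries
            ],
        }
    )


def bouts_frame(summaries: Sequence[ActivitySummary]) -> pd.DataFrame:
    """Bout-level table: one row per immobility bout."""
    rows = [
        {
            "animal_id": s.animal_id,
            "start_s": b.start_s,
            "duration_s": b.duration_s,
            "zone": b.zone,
        }
        for s in summaries
        for b in s.bouts
    ]
    return pd.DataFrame(rows, columns=["animal_id", "start_s", "duration_s", "zone"])
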