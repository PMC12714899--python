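"""Zone-occupancy profiles: percent of analyzed frames per temperature zone.

Occupancy is computed from frame counts (the tracker's native currency), not
continuous dwell times.  Time windows are half-open ``[start, end)``; zone
bins are half-open with the hot-end boundary closed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .arena import (
    ArenaGeometry,
    ThermalCalibration,
    zone_center_temperatures,
    zone_of_position,
)
from .errors import DegenerateDataError, EmptyAnalysisWindowError
from .tracks import AnimalTrack

log = logging.getLogger(__name__)

__all__ = [
    "OccupancyProfile",
    "GroupOccupancy",
    "occupancy_profile",
    "group_occupancy",
    "sliding_window_occupancy",
    "pooled_points",
    "profiles_to_frame",
]


@dataclass(frozen=True)
class OccupancyProfile:
    """Per-animal occupancy: percent of frames in each zone, at the zone
    center temperatures."""

    animal_id: str
    percent_by_zone: np.ndarray
    zone_center_temps_c: np.ndarray
    window: tuple[float, float]
    n_frames: int

    def __post_init__(self) -> None:
        p = np.asarray(self.percent_by_zone, dtype=float)
        object.__setattr__(self, "percent_by_zone", p)
        object.__setattr__(
            self, "zone_center_temps_c", np.asarray(self.zone_center_temps_c, float)
        )
        if len(p) != len(self.zone_center_temps_c):
            raise ValueError("zone vectors must have equal length")
        if np.any(p < 0) or abs(p.sum() - 100.0) > 1e-9:
            raise ValueError("occupancy percentages must be >= 0 and sum to 100")


@dataclass(frozen=True)
class GroupOccupancy:
    """Across-animal mean ± SEM occupancy for one condition."""

    condition: str
    mean_percent_by_zone: np.ndarray
    sem_percent_by_zone: np.ndarray
    n_animals: int
    zone_center_temps_c: np.ndarray


def occupancy_profile(
    track: AnimalTrack,
    arena: ArenaGeometry = ArenaGeometry(),
    calibration: ThermalCalibration | None = None,
    window: tuple[float, float] | None = None,
) -> OccupancyProfile:
    """Percent of frames spent in each zone over a half-open time window.

    ``window`` defaults to the full track extent.  The profile's abscissa is
    the calibrated temperature at each zone midpoint.
    """
    calib = calibration or ThermalCalibration.nominal(length_cm=arena.length_cm)
    if window is None:
        start, end = float(track.time_s[0]), float(track.time_s[-1]) + 1.0 / track.fps
    else:
        start, end = float(window[0]), float(window[1])
    mask = (track.time_s >= start) & (track.time_s < end)
    n = int(mask.sum())
    if n == 0:
        raise EmptyAnalysisWindowError(
            f"track {track.animal_id!r}: no frames in window [{start}, {end})"
        )
    zones = zone_of_position(track.x_cm[mask], arena)  # validates bounds
    counts = np.bincount(zones, minlength=arena.n_zones + 1)[1:]
    percent = 100.0 * counts / n
    return OccupancyProfile(
        animal_id=track.animal_id,
        percent_by_zone=percent,
        zone_center_temps_c=zone_center_temperatures(arena, calib),
        window=(start, end),
        n_frames=n,
    )


def group_occupancy(
    profiles: Sequence[OccupancyProfile], condition: str = ""
) -> GroupOccupancy:
    """Mean and SEM (sample SD / √n) of occupancy across animals."""
    if not profiles:
        raise DegenerateDataError("group_occupancy needs at least one profile")
    temps = profiles[0].zone_center_temps_c
    for p in profiles[1:]:
        if len(p.percent_by_zone) != len(temps) or not np.allclose(
            p.zone_center_temps_c, temps
        ):
            raise DegenerateDataError("profiles have mismatched zone structures")
    mat = np.vstack([p.percent_by_zone for p in profiles])
    mean = mat.mean(axis=0)
    if len(profiles) == 1:
        log.warning("group %r has a single animal; SEM reported as 0", condition)
        sem = np.zeros_like(mean)
    else:
        sem = mat.std(axis=0, ddof=1) / np.sqrt(len(profiles))
    return GroupOccupancy(
        condition=condition,
        mean_percent_by_zone=mean,
        sem_percent_by_zone=sem,
        n_animals=len(profiles),
        zone_center_temps_c=temps,
    )


def sliding_window_occupancy(
    track: AnimalTrack,
    arena: ArenaGeometry = ArenaGeometry(),
    calibration: ThermalCalibration | None = None,
    window_length_s: float = 600.0,
    step_s: float = 600.0,
) -> list[OccupancyProfile]:
    """Occupancy profiles over sliding windows [0, W), [step, step+W), …

    Windows start while they overlap the track; the last window is clipped to
    the track end.  ``step_s == window_length_s`` gives disjoint windows;
    smaller steps give overlapping ones.
    """
    duration = track.duration_s
    if window_length_s > duration + 1e-9:
        raise EmptyAnalysisWindowError(
            f"window {window_length_s} s exceeds track duration {duration:.1f} s"
        )
    if step_s <= 0:
        raise ValueError("step_s must be positive")
    out = []
    start = float(track.time_s[0])
    t_end = start + duration
    while start < t_end - 1e-9:
        out.append(
            occupancy_profile(
                track, arena, calibration,
                window=(start, min(start + window_length_s, t_end)),
            )
        )
        start += step_s
    return out


def pooled_points(
    profiles: Sequence[OccupancyProfile],
) -> tuple[np.ndarray, np.ndarray]:
    """Pool per-animal × per-zone points for curve fitting.

    Returns (temps, percents) with one entry per animal-zone; fitting on the
    pooled points (rather than group means) is what gives the nested F tests
    their per-point residual degrees of freedom.
    """
    temps = np.concatenate([p.zone_center_temps_c for p in profiles])
    percents = np.concatenate([p.percent_by_zone for p in profiles])
    return temps, percents


def profiles_to_frame(profiles: Sequence[OccupancyProfile]) -> pd.DataFrame:
    """Long-format table: one row per animal × zone."""
    rows = []
    for p in profiles:
        for z, (temp, pct) in enumerate(
            zip(p.zone_center_temps_c, p.percent_by_zone), start=1
        ):
            rows.append(
                {
                    "animal_id": p.animal_id,
                    "zone": z,
                    "zone_center_temp_c": temp,
                    "percent_time": pct,
                    "window_start_s": p.window[0],
                    "window_end_s": p.window[1],
                }
            )
    return pd.DataFrame(rows)
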