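"""Trajectory tables: reading, validation, preprocessing, writing.

A track is the time-stamped center-of-mass position of one animal along the
gradient axis, recorded at a nominal camera rate (default 15 frames/s).
Preprocessing mirrors the assay convention: the first 30 s are discarded as
exploration-dominated, the remainder is clipped to the analysis window, and
timestamps are re-zeroed to the window start.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .arena import ArenaGeometry, ThermalCalibration
from .errors import EmptyAnalysisWindowError, OutOfArenaError, SchemaError

log = logging.getLogger(__name__)

__all__ = [
    "TrajectorySample",
    "AnimalTrack",
    "Cohort",
    "PreprocessSpec",
    "read_tracks",
    "write_tracks",
    "read_metadata",
    "write_metadata",
    "preprocess",
    "analyzed_frame_count",
]

DEFAULT_SCHEMA = {
    "animal_id": "animal_id",
    "time_s": "time_s",
    "x_cm": "x_cm",
    "y_cm": "y_cm",
}


@dataclass(frozen=True)
class TrajectorySample:
    """One frame: time from recording start and position."""

    time_s: float
    x_cm: float
    y_cm: float | None = None


@dataclass
class AnimalTrack:
    """Center-of-mass trajectory of a single animal.

    ``time_s``/``x_cm`` (and optional ``y_cm``) are parallel arrays sorted by
    time.  ``condition``/``sex``/``group`` carry experimental metadata.
    """

    animal_id: str
    time_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray | None = None
    fps: float = 15.0
    condition: str | None = None
    sex: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.x_cm = np.asarray(self.x_cm, dtype=float)
        if self.y_cm is not None:
            self.y_cm = np.asarray(self.y_cm, dtype=float)
        if self.time_s.shape != self.x_cm.shape:
            raise ValueError("time_s and x_cm must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError(
                f"track {self.animal_id!r}: timestamps must be strictly increasing"
            )

    @property
    def n_samples(self) -> int:
        return len(self.time_s)

    @property
    def duration_s(self) -> float:
        """Recording span including the final frame's dwell (1/fps)."""
        if self.n_samples == 0:
            return 0.0
        return float(self.time_s[-1] - self.time_s[0]) + 1.0 / self.fps

    def samples(self) -> list[TrajectorySample]:
        ys = self.y_cm if self.y_cm is not None else [None] * self.n_samples
        return [
            TrajectorySample(float(t), float(x), None if y is None else float(y))
            for t, x, y in zip(self.time_s, self.x_cm, ys)
        ]


@dataclass
class Cohort:
    """A set of tracks analyzed under one arena, calibration and
    preprocessing convention."""

    tracks: list[AnimalTrack]
    arena: ArenaGeometry
    calibration: ThermalCalibration
    preprocess: "PreprocessSpec" = field(default_factory=lambda: PreprocessSpec())

    def __iter__(self):
        return iter(self.tracks)

    def __len__(self) -> int:
        return len(self.tracks)


@dataclass(frozen=True)
class PreprocessSpec:
    """Preprocessing convention for the assay.

    exclude_initial_s
        Seconds dropped from the start of the recording (default 30;
        exploration-dominated).
    analysis_window_s
        Duration analyzed after the exclusion (default 600, i.e. a 10-min
        assay).
    smoothing_window_frames
        Odd window for median smoothing of x; 0 disables it.  Off by default:
        occupancy is bin-robust, and distance metrics apply their own
        smoothing so jitter is handled where it matters.
    """

    exclude_initial_s: float = 30.0
    analysis_window_s: float = 600.0
    smoothing_window_frames: int = 0

    def __post_init__(self) -> None:
        if self.exclude_initial_s < 0:
            raise ValueError("exclude_initial_s must be >= 0")
        if self.analysis_window_s <= 0:
            raise ValueError("analysis_window_s must be > 0")
        w = self.smoothing_window_frames
        if w < 0 or (w > 0 and w % 2 == 0):
            raise ValueError("smoothing window must be 0 or an odd integer")


# ---------------------------------------------------------------------------
# I/O


def read_tracks(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    arena: ArenaGeometry | None = None,
    fps: float = 15.0,
) -> list[AnimalTrack]:
    """Read per-animal trajectories from a CSV table.

    ``schema`` maps canonical field names (``animal_id``, ``time_s``,
    ``x_cm``, optional ``y_cm``) to the file's column names.  Rows with
    non-numeric coordinates are reported with their line numbers; positions
    outside the arena (when one is given) likewise.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path)
    for key in ("animal_id", "time_s", "x_cm"):
        if colmap[key] not in df.columns:
            raise SchemaError(
                f"{path}: missing mandatory column {colmap[key]!r} "
                f"(for {key}); found {list(df.columns)}"
            )
    has_y = colmap.get("y_cm") in df.columns

    def _numeric(colkey: str) -> pd.Series:
        raw = df[colmap[colkey]]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna()
        if bad.any():
            lines = (df.index[bad] + 2).tolist()  # +1 header, +1 one-based
            raise SchemaError(
                f"{path}: non-numeric {colkey} values at line(s) {lines[:10]}"
            )
        return num

    time = _numeric("time_s")
    x = _numeric("x_cm")
    y = _numeric("y_cm") if has_y else None

    if arena is not None:
        bad = (x < 0) | (x > arena.length_cm)
        if bad.any():
            lines = (df.index[bad] + 2).tolist()
            raise OutOfArenaError(
                f"{path}: x outside [0, {arena.length_cm}] cm at line(s) {lines[:10]}"
            )

    clean = pd.DataFrame(
        {
            "animal_id": df[colmap["animal_id"]].astype(str),
            "time_s": time,
            "x_cm": x,
        }
    )
    if y is not None:
        clean["y_cm"] = y

    # tracking dropouts arrive as empty cells -> forward fill up to 1 s
    n_gap = int(round(fps))
    tracks: list[AnimalTrack] = []
    for animal_id, sub in clean.groupby("animal_id", sort=True):
        sub = sub.sort_values("time_s")
        xs = sub["x_cm"]
        if xs.isna().any():
            filled = xs.ffill(limit=n_gap)
            n_left = int(filled.isna().sum())
            if n_left:
                log.warning(
                    "track %s: %d frames in gaps longer than 1 s dropped",
                    animal_id,
                    n_left,
                )
            sub = sub.assign(x_cm=filled).dropna(subset=["x_cm"])
        tracks.append(
            AnimalTrack(
                animal_id=str(animal_id),
                time_s=sub["time_s"].to_numpy(),
                x_cm=sub["x_cm"].to_numpy(),
                y_cm=sub["y_cm"].to_numpy() if "y_cm" in sub else None,
                fps=fps,
            )
        )
    return tracks


def write_tracks(tracks: Sequence[AnimalTrack], path: str | Path) -> None:
    """Write tracks to CSV with deterministic row order (animal, then time)."""
    frames = []
    any_y = any(t.y_cm is not None for t in tracks)
    for t in sorted(tracks, key=lambda t: t.animal_id):
        d = {"animal_id": t.animal_id, "time_s": t.time_s, "x_cm": t.x_cm}
        if any_y:
            d["y_cm"] = t.y_cm if t.y_cm is not None else np.full(t.n_samples, np.nan)
        frames.append(pd.DataFrame(d))
    cols = ["animal_id", "time_s", "x_cm"] + (["y_cm"] if any_y else [])
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=cols)
    out.to_csv(path, index=False, float_format="%.10g")


def write_metadata(tracks: Sequence[AnimalTrack], path: str | Path) -> None:
    """JSON sidecar: per-animal condition/sex/group labels."""
    meta = {
        t.animal_id: {"condition": t.condition, "sex": t.sex, "group": t.group}
        for t in tracks
    }
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_metadata(tracks: Sequence[AnimalTrack], path: str | Path) -> None:
    """Attach labels from a JSON sidecar to tracks in place."""
    meta = json.loads(Path(path).read_text())
    for t in tracks:
        m = meta.get(t.animal_id)
        if m:
            t.condition = m.get("condition")
            t.sex = m.get("sex")
            t.group = m.get("group")


# ---------------------------------------------------------------------------
# Preprocessing


def _is_regular(time_s: np.ndarray, fps: float, tol: float = 0.1) -> bool:
    if len(time_s) < 2:
        return True
    dt = np.diff(time_s)
    return bool(np.all(np.abs(dt * fps - 1.0) <= tol))

def _resample_nearest(track: AnimalTrack) -> AnimalTrack:
    """Snap an irregular track onto the nominal frame grid by
    nearest-sample lookup."""
    t0, t1 = track.time_s[0], track.time_s[-1]
    n = int(math.floor((t1 - t0) * track.fps)) + 1
    grid = t0 + np.arange(n) / track.fps
    idx = np.searchsorted(track.time_s, grid)
    idx = np.clip(idx, 1, len(track.time_s) - 1)
    left_closer = (grid - track.time_s[idx - 1]) <= (track.time_s[idx] - grid)
    nearest = np.where(left_closer, idx - 1, idx)
    return replace(
        track,
        time_s=grid,
        x_cm=track.x_cm[nearest],
        y_cm=None if track.y_cm is None else track.y_cm[nearest],
    )


def preprocess(track: AnimalTrack, spec: PreprocessSpec = PreprocessSpec()) -> AnimalTrack:
    """Apply the assay's analysis convention to a raw track.

    Frames before ``exclude_initial_s`` are dropped, the remainder is clipped
    to ``analysis_window_s``, optional median smoothing is applied to x, and
    timestamps are re-zeroed to the window start.  Raises
    :class:`EmptyAnalysisWindowError` if nothing survives the exclusion.
    """
    if not _is_regular(track.time_s, track.fps):
        track = _resample_nearest(track)
    keep = (track.time_s >= track.time_s[0] + spec.exclude_initial_s) & (
        track.time_s < track.time_s[0] + spec.exclude_initial_s + spec.analysis_window_s
    )
    if not keep.any():
        raise EmptyAnalysisWindowError(
            f"track {track.animal_id!r}: no frames left after excluding "
            f"{spec.exclude_initial_s} s"
        )
    t = track.time_s[keep]
    x = track.x_cm[keep]
    y = track.y_cm[keep] if track.y_cm is not None else None
    w = spec.smoothing_window_frames
    if w and len(x) > w:
        x = median_filter(x, size=w, mode="nearest")
        if y is not None:
            y = median_filter(y, size=w, mode="nearest")
    return replace(track, time_s=t - t[0], x_cm=x, y_cm=y)


def analyzed_frame_count(duration_s: float, fps: float, exclude_initial_s: float) -> int:
    """Number of analyzed frames: ``floor((duration − exclusion) × fps)``.

    The standard assay (600 s at 15 fps, 30 s excluded) yields 8550 frames.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    if duration_s <= exclude_initial_s:
        raise EmptyAnalysisWindowError(
            "recording no longer than the exclusion window"
        )
    return int(math.floor((duration_s - exclude_initial_s) * fps))
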