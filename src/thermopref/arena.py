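"""Corridor geometry and the position→temperature calibration.

The assay arena is a long, narrow corridor whose aluminium floor carries a
linear temperature gradient along its length (cold end at x = 0).  Analysis
divides the corridor into equal-width zones and converts an animal's
center-of-mass position into the floor temperature it experiences through a
linear calibration.

Coordinate convention: x = 0 at the cold end and x increasing toward the hot
end, so the calibration intercept equals the cold-end temperature.  Zones are
numbered 1..n_zones from cold to hot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, OutOfArenaError

__all__ = [
    "ArenaGeometry",
    "ThermalCalibration",
    "CalibrationPoint",
    "zone_of_position",
    "temperature_at_position",
    "fit_calibration",
    "gradient_resolution",
    "zone_center_temperatures",
]

#: nominal endpoint temperatures of the gradient, °C
NOMINAL_COLD_C = 4.0
NOMINAL_HOT_C = 58.0
DEFAULT_LENGTH_CM = 137.0


@dataclass(frozen=True)
class ArenaGeometry:
    """Corridor dimensions and zone partition.

    Parameters
    ----------
    length_cm : float
        Corridor length along the gradient axis (default 137 cm).
    width_cm : float
        Corridor width, transverse to the gradient (default 10 cm).
    n_zones : int
        Number of equal-width analysis zones (default 14, chosen so the zone
        width of ~9.8 cm matches the effective body length of a moving mouse).
    """

    length_cm: float = DEFAULT_LENGTH_CM
    width_cm: float = 10.0
    n_zones: int = 14

    def __post_init__(self) -> None:
        if self.length_cm <= 0 or self.width_cm <= 0:
            raise ValueError("arena dimensions must be positive")
        if self.n_zones < 1:
            raise ValueError("n_zones must be a positive integer")

    @property
    def zone_width_cm(self) -> float:
        return self.length_cm / self.n_zones

    @property
    def zone_edges_cm(self) -> np.ndarray:
        """Zone boundary positions, length ``n_zones + 1``."""
        return np.linspace(0.0, self.length_cm, self.n_zones + 1)

    @property
    def zone_centers_cm(self) -> np.ndarray:
        """Midpoint position of each zone, length ``n_zones``."""
        edges = self.zone_edges_cm
        return 0.5 * (edges[:-1] + edges[1:])


@dataclass(frozen=True)
class ThermalCalibration:
    """Linear map from position (cm from the cold end) to floor temperature.

    ``source`` records whether the line is the nominal endpoint line
    (cold/hot setpoints at the corridor ends) or was fitted to thermocouple
    measurements.
    """

    slope_c_per_cm: float
    intercept_c: float
    r_squared: float = 1.0
    source: str = "nominal"

    def __post_init__(self) -> None:
        if self.source not in ("nominal", "fitted"):
            raise ValueError(f"unknown calibration source {self.source!r}")

    @classmethod
    def nominal(
        cls,
        cold_c: float = NOMINAL_COLD_C,
        hot_c: float = NOMINAL_HOT_C,
        length_cm: float = DEFAULT_LENGTH_CM,
    ) -> "ThermalCalibration":
        """Endpoint line: ``cold_c`` at x = 0, ``hot_c`` at x = length."""
        if hot_c <= cold_c:
            raise ValueError("hot_c must exceed cold_c")
        return cls(
            slope_c_per_cm=(hot_c - cold_c) / length_cm,
            intercept_c=cold_c,
            r_squared=1.0,
            source="nominal",
        )

    def temperature_at(self, x_cm):
        return self.slope_c_per_cm * np.asarray(x_cm) + self.intercept_c

    def position_at(self, temp_c):
        """Inverse map; requires a non-zero slope."""
        if self.slope_c_per_cm == 0:
            raise DegenerateDataError("flat calibration has no inverse")
        return (np.asarray(temp_c) - self.intercept_c) / self.slope_c_per_cm


@dataclass(frozen=True)
class CalibrationPoint:
    """A single thermocouple reading: position along the gradient and the
    measured surface temperature."""

    x_cm: float
    temp_c: float


def _check_in_arena(x_cm, length_cm: float) -> np.ndarray:
    x = np.asarray(x_cm, dtype=float)
    if np.any(x < 0) or np.any(x > length_cm):
        bad = x[(x < 0) | (x > length_cm)]
        raise OutOfArenaError(
            f"position(s) outside [0, {length_cm}] cm: {np.atleast_1d(bad)[:5]}"
        )
    return x


def zone_of_position(x_cm, geometry: ArenaGeometry = ArenaGeometry()):
    """1-based zone index of a position (zone 1 = cold end).

    Bins are half-open ``[lo, hi)``; the hot-end boundary ``x == length``
    belongs to the last zone.  Scalar in, scalar out; array in, array out.
    """
    x = _check_in_arena(x_cm, geometry.length_cm)
    # x*n/length keeps exact zone boundaries exact in floating point,
    # unlike dividing by the (rounded) zone width
    idx = np.floor(x * geometry.n_zones / geometry.length_cm).astype(int) + 1
    idx = np.minimum(idx, geometry.n_zones)
    if np.isscalar(x_cm) or np.ndim(x_cm) == 0:
        return int(idx)
    return idx


def temperature_at_position(x_cm, calib: ThermalCalibration,
                            geometry: ArenaGeometry | None = None):
    """Floor temperature (°C) at a position; checks arena bounds when a
    geometry is supplied."""
    if geometry is not None:
        _check_in_arena(x_cm, geometry.length_cm)
    return calib.temperature_at(x_cm)


def fit_calibration(
    points: Iterable[CalibrationPoint] | Sequence[tuple[float, float]],
) -> ThermalCalibration:
    """Ordinary-least-squares line through thermocouple measurements.

    Accepts :class:`CalibrationPoint` objects or plain ``(x_cm, temp_c)``
    pairs.  With zero variance in temperature the slope is 0 and R² is
    reported as 0 by convention (never NaN).
    """
    xs, ts = [], []
    for p in points:
        if isinstance(p, CalibrationPoint):
            xs.append(p.x_cm)
            ts.append(p.temp_c)
        else:
            x, t = p
            xs.append(float(x))
            ts.append(float(t))
    x = np.asarray(xs, dtype=float)
    t = np.asarray(ts, dtype=float)
    if len(np.unique(x)) < 2:
        raise DegenerateDataError(
            "calibration needs at least 2 distinct positions"
        )
    if np.ptp(t) == 0:
        return ThermalCalibration(0.0, float(t[0]), 0.0, source="fitted")
    res = stats.linregress(x, t)
    return ThermalCalibration(
        slope_c_per_cm=float(res.slope),
        intercept_c=float(res.intercept),
        r_squared=float(res.rvalue**2),
        source="fitted",
    )


def gradient_resolution(cold_c: float, hot_c: float, length_cm: float) -> float:
    """Temperature resolution of the gradient in °C per cm,
    ``(hot − cold) / length``."""
    if length_cm <= 0:
        raise ValueError("length_cm must be positive")
    if hot_c <= cold_c:
        raise ValueError("hot_c must exceed cold_c")
    return (hot_c - cold_c) / length_cm


def zone_center_temperatures(
    geometry: ArenaGeometry, calib: ThermalCalibration
) -> np.ndarray:
    """Temperature at each zone midpoint — the abscissa of occupancy
    profiles and preference fits."""
    return np.asarray(calib.temperature_at(geometry.zone_centers_cm), dtype=float)
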