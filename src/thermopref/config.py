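"""YAML run configuration.

Schema (all blocks optional; defaults shown):

.. code-block:: yaml

    arena:
      length_cm: 137.0
      width_cm: 10.0
      n_zones: 14
    calibration:
      mode: nominal          # nominal | fitted
      points:                # required for fitted mode
        - [6.9, 6.5]
        - [130.1, 55.2]
    preprocess:
      exclude_initial_s: 30.0
      analysis_window_s: 600.0
      smoothing_window_frames: 0
    fit:
      amplitude_mode: free_3p
    activity:
      speed_threshold_cm_s: 0.5
      min_bout_s: 3.0
    seed: 0
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .arena import ArenaGeometry, ThermalCalibration, fit_calibration
from .errors import ConfigError
from .tracks import PreprocessSpec

__all__ = ["RunConfig", "load_run_config", "dump_run_config"]


@dataclass
class RunConfig:
    """Resolved configuration of one analysis run."""

    arena: ArenaGeometry = field(default_factory=ArenaGeometry)
    calibration: ThermalCalibration = field(
        default_factory=ThermalCalibration.nominal
    )
    preprocess: PreprocessSpec = field(default_factory=PreprocessSpec)
    amplitude_mode: str = "free_3p"
    speed_threshold_cm_s: float = 0.5
    min_bout_s: float = 3.0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "arena": {
                "length_cm": self.arena.length_cm,
                "width_cm": self.arena.width_cm,
                "n_zones": self.arena.n_zones,
            },
            "calibration": {
                "mode": self.calibration.source,
                "slope_c_per_cm": self.calibration.slope_c_per_cm,
                "intercept_c": self.calibration.intercept_c,
                "r_squared": self.calibration.r_squared,
            },
            "preprocess": asdict(self.preprocess),
            "fit": {"amplitude_mode": self.amplitude_mode},
            "activity": {
                "speed_threshold_cm_s": self.speed_threshold_cm_s,
                "min_bout_s": self.min_bout_s,
            },
            "seed": self.seed,
        }


def load_run_config(path: str | Path | None) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file (or defaults if None)."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}

    arena_block = raw.get("arena", {})
    arena = ArenaGeometry(
        length_cm=float(arena_block.get("length_cm", 137.0)),
        width_cm=float(arena_block.get("width_cm", 10.0)),
        n_zones=int(arena_block.get("n_zones", 14)),
    )

    calib_block = raw.get("calibration", {})
    mode = calib_block.get("mode", "nominal")
    if mode == "nominal":
        calibration = ThermalCalibration.nominal(length_cm=arena.length_cm)
    elif mode == "fitted":
        points = calib_block.get("points")
        if not points:
            raise ConfigError("fitted calibration requires calibration.points")
        calibration = fit_calibration([(float(x), float(t)) for x, t in points])
    else:
        raise ConfigError(f"calibration.mode must be nominal|fitted, got {mode!r}")

    pp = raw.get("preprocess", {})
    preprocess = PreprocessSpec(
        exclude_initial_s=float(pp.get("exclude_initial_s", 30.0)),
        analysis_window_s=float(pp.get("analysis_window_s", 600.0)),
        smoothing_window_frames=int(pp.get("smoothing_window_frames", 0)),
    )

    fit_block = raw.get("fit", {})
    act = raw.get("activity", {})
    return RunConfig(
        arena=arena,
        calibration=calibration,
        preprocess=preprocess,
        amplitude_mode=fit_block.get("amplitude_mode", "free_3p"),
        speed_threshold_cm_s=float(act.get("speed_threshold_cm_s", 0.5)),
        min_bout_s=float(act.get("min_bout_s", 3.0)),
        seed=int(raw.get("seed", 0)),
    )


def dump_run_config(config: RunConfig, path: str | Path) -> None:
    """Write the resolved configuration next to a run's outputs."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
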