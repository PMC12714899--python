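"""Stochastic thermotaxis simulator.

Generates center-of-mass tracks whose long-run position distribution is the
Gaussian temperature preference the analysis fits, so every downstream stage
(occupancy, curve fitting, nested-model tests, activity metrics) can be
exercised and validated without animal data.

Model
-----
While "moving", position follows a discrete-time Ornstein–Uhlenbeck process
with time step ``dt = 1/fps``::

    x[n+1] = x[n] + k·(x_pref − x[n])·dt + σ_w·sqrt(dt)·ξ[n]

reflected at the corridor ends.  ``x_pref`` is the preferred temperature
mapped through the calibration, and ``σ_w = (sd_pref/slope)·sqrt(2k)`` so the
unreflected stationary law is exactly Gaussian with the requested
temperature-domain SD.  ``locomotion_scale`` s rescales the process clock
(k → k·s², σ_w → σ_w·s): travel speed changes while the stationary
preference distribution — the quantity the assay estimates — is preserved.

Rest bouts: while moving, a rest bout begins with per-second hazard
``rest_hazard_per_s`` weighted by the Gaussian preference
``exp(−(T(x)−t_pref)²/(2·sd_pref²))`` (animals settle where they are
comfortable); bout durations are exponential with mean ``rest_mean_s`` and
the position is frozen for the bout.

With ``attraction_rate_per_s = 0`` there is no preference drift and the
process is reflected Brownian motion with diffusion magnitude
``baseline_diffusion_cm_per_sqrt_s`` (uniform stationary law).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .arena import ArenaGeometry, ThermalCalibration
from .errors import ConfigError
from .tracks import AnimalTrack, Cohort, PreprocessSpec

__all__ = [
    "SimulationConfig",
    "ConditionPreset",
    "PRESET_NAMES",
    "preset",
    "simulate_track",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated condition.

    t_pref_c, sd_pref_c
        Center and width (°C) of the stationary temperature preference.
    attraction_rate_per_s
        OU mean-reversion rate k toward the preferred position (1/s).
        0 disables the preference drift entirely.
    locomotion_scale
        Process-clock multiplier: scales σ_w by s and k by s², changing
        travel speed without altering the stationary preference.
    rest_hazard_per_s, rest_mean_s
        Baseline rate of entering a rest bout and the mean (exponential)
        bout duration.
    baseline_diffusion_cm_per_sqrt_s
        Diffusion magnitude used when ``attraction_rate_per_s == 0``
        (default 18, comparable to the naive presets' σ_w).
    end_bias_rate_per_s
        Weak drift toward the nearest corridor end; emulates the
        corner-seeking seen with no thermal gradient.  0 for gradient runs.
    """

    t_pref_c: float = 30.4
    sd_pref_c: float = 11.6
    attraction_rate_per_s: float = 0.2
    locomotion_scale: float = 1.0
    rest_hazard_per_s: float = 0.05
    rest_mean_s: float = 6.0
    duration_s: float = 600.0
    fps: float = 15.0
    n_animals: int = 12
    seed: int = 0
    start_mode: str = "center"
    baseline_diffusion_cm_per_sqrt_s: float = 18.0
    end_bias_rate_per_s: float = 0.0

    def __post_init__(self) -> None:
        if self.sd_pref_c <= 0:
            raise ConfigError("sd_pref_c must be > 0")
        if self.fps <= 0 or self.duration_s <= 0:
            raise ConfigError("fps and duration_s must be > 0")
        if self.attraction_rate_per_s < 0:
            raise ConfigError("attraction_rate_per_s must be >= 0")
        if self.locomotion_scale < 0:
            raise ConfigError("locomotion_scale must be >= 0")
        if self.start_mode not in ("center", "random"):
            raise ConfigError("start_mode must be 'center' or 'random'")


@dataclass(frozen=True)
class ConditionPreset:
    """A named, literature-anchored parameterization of the simulator."""

    name: str
    config: SimulationConfig
    description: str = ""


def _presets() -> dict[str, ConditionPreset]:
    # T_peak/SD anchors: naive male 30.4/11.6, naive female 32.2/13.8,
    # CFA 36.6/6.1 (warm-shifted, narrowed, hypolocomotive, more resting).
    # Morphine conditions are phenomenological: near-flat preference plus
    # hyperlocomotion and little resting.
    make = SimulationConfig
    return {
        "naive_male": ConditionPreset(
            "naive_male",
            make(t_pref_c=30.4, sd_pref_c=11.6),
            "naive male: T_peak 30.4 °C, SD 11.6 °C",
        ),
        "naive_female": ConditionPreset(
            "naive_female",
            make(t_pref_c=32.2, sd_pref_c=13.8),
            "naive female: warmer, broader preference",
        ),
        "cfa": ConditionPreset(
            "cfa",
            make(
                t_pref_c=36.6,
                sd_pref_c=6.1,
                locomotion_scale=0.6,
                rest_hazard_per_s=0.1,
                rest_mean_s=8.0,
            ),
            "inflamed hind paw: warm-shifted narrow preference, reduced "
            "locomotion, increased resting",
        ),
        "naive_morphine": ConditionPreset(
            "naive_morphine",
            make(
                t_pref_c=31.0,
                sd_pref_c=40.0,
                attraction_rate_per_s=0.05,
                locomotion_scale=1.5,
                rest_hazard_per_s=0.01,
                rest_mean_s=3.0,
            ),
            "morphine-treated naive: near-flat preference, hyperlocomotion",
        ),
        "cfa_morphine": ConditionPreset(
            "cfa_morphine",
            make(
                t_pref_c=31.0,
                sd_pref_c=40.0,
                attraction_rate_per_s=0.05,
                locomotion_scale=2.0,
                rest_hazard_per_s=0.01,
                rest_mean_s=3.0,
            ),
            "morphine after inflammation: flat preference, strongest "
            "hyperlocomotion",
        ),
        "no_gradient": ConditionPreset(
            "no_gradient",
            make(
                t_pref_c=31.0,
                sd_pref_c=20.0,
                attraction_rate_per_s=0.0,
                end_bias_rate_per_s=0.05,
            ),
            "room-temperature floor: corner-seeking U-shape (qualitative)",
        ),
    }


PRESET_NAMES = tuple(_presets())


def preset(name: str) -> ConditionPreset:
    """Look up a named condition preset; unknown names list valid ones."""
    table = _presets()
    try:
        return table[name]
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; valid presets: {', '.join(table)}"
        ) from None


def _rng_for_animal(seed: int, animal_index: int) -> np.random.Generator:
    # counter-based derivation: each animal's stream depends only on
    # (seed, index), so reordering animals never changes a path
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(animal_index)]))


def simulate_track(
    config: SimulationConfig,
    arena: ArenaGeometry = ArenaGeometry(),
    calibration: ThermalCalibration | None = None,
    animal_index: int = 0,
    animal_id: str | None = None,
    condition: str | None = None,
) -> AnimalTrack:
    """Simulate one animal's track; fully reproducible from
    ``(config.seed, animal_index)``."""
    calib = calibration or ThermalCalibration.nominal(length_cm=arena.length_cm)
    L = arena.length_cm
    slope = calib.slope_c_per_cm
    k = config.attraction_rate_per_s
    s = config.locomotion_scale

    if k > 0:
        x_pref = float(calib.position_at(config.t_pref_c))
        if not (0.0 <= x_pref <= L):
            raise ConfigError(
                f"preferred temperature {config.t_pref_c} °C maps to "
                f"{x_pref:.1f} cm, outside the corridor [0, {L}] cm"
            )
        sigma = (config.sd_pref_c / slope) * math.sqrt(2.0 * k) * s
        k_eff = k * s * s
    else:
        x_pref = L / 2.0
        sigma = config.baseline_diffusion_cm_per_sqrt_s * s
        k_eff = 0.0

    dt = 1.0 / config.fps
    n = int(round(config.duration_s * config.fps))
    rng = _rng_for_animal(config.seed, animal_index)

    x0 = L / 2.0 if config.start_mode == "center" else float(rng.uniform(0.0, L))
    noise = rng.standard_normal(n) * (sigma * math.sqrt(dt))
    entry_u = rng.random(n)

    # rest-entry weight as a function of position, precomputed constants
    inv2sd2 = 1.0 / (2.0 * config.sd_pref_c**2)
    t_pref = config.t_pref_c
    intercept = calib.intercept_c
    hazard = config.rest_hazard_per_s
    rest_mean = config.rest_mean_s
    end_bias = config.end_bias_rate_per_s
    a = k_eff * dt
    half = L / 2.0

    xs = np.empty(n)
    x = x0
    rest_until = -1.0
    t = 0.0
    exp_draw = rng.exponential  # drawn lazily, in entry order
    for i in range(n):
        xs[i] = x
        t = i * dt
        if t < rest_until:
            continue
        if hazard > 0.0:
            temp = slope * x + intercept
            d = temp - t_pref
            w = math.exp(-d * d * inv2sd2)
            if entry_u[i] < hazard * w * dt:
                rest_until = t + exp_draw(rest_mean)
                continue
        x_prev = x
        x = x + a * (x_pref - x) + noise[i]
        if end_bias > 0.0:
            target = L if x_prev > half else 0.0
            x += end_bias * dt * (target - x_prev)
        # reflect into [0, L]
        while x < 0.0 or x > L:
            if x < 0.0:
                x = -x
            else:
                x = 2.0 * L - x

    return AnimalTrack(
        animal_id=animal_id or f"sim{animal_index:03d}",
        time_s=np.arange(n) / config.fps,
        x_cm=xs,
        fps=config.fps,
        condition=condition,
    )


def simulate_cohort(
    config_or_preset: SimulationConfig | ConditionPreset | str,
    n_animals: int | None = None,
    seed: int | None = None,
    arena: ArenaGeometry = ArenaGeometry(),
    calibration: ThermalCalibration | None = None,
    duration_s: float | None = None,
) -> Cohort:
    """Simulate an independent cohort.

    Accepts a :class:`SimulationConfig`, a :class:`ConditionPreset`, or a
    preset name.  ``n_animals``/``seed``/``duration_s`` override the config's
    values when given.  Animal streams are derived per index, so the cohort
    is reproducible and order-independent.
    """
    if isinstance(config_or_preset, str):
        config_or_preset = preset(config_or_preset)
    condition = None
    if isinstance(config_or_preset, ConditionPreset):
        condition = config_or_preset.name
        config = config_or_preset.config
    else:
        config = config_or_preset
    overrides = {}
    if n_animals is not None:
        overrides["n_animals"] = n_animals
    if seed is not None:
        overrides["seed"] = seed
    if duration_s is not None:
        overrides["duration_s"] = duration_s
    if overrides:
        config = replace(config, **overrides)
    if config.n_animals < 1:
        raise ConfigError("n_animals must be >= 1")
    calib = calibration or ThermalCalibration.nominal(length_cm=arena.length_cm)
    tracks = [
        simulate_track(
            config,
            arena,
            calib,
            animal_index=i,
            condition=condition,
        )
        for i in range(config.n_animals)
    ]
    return Cohort(tracks=tracks, arena=arena, calibration=calib,
                  preprocess=PreprocessSpec())
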