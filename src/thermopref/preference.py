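"""Gaussian temperature-preference fitting.

The assay's readout is a Gaussian fit of zone occupancy against zone-center
temperature: the center is the most preferred temperature (T_peak), the
width (SD) measures thermal avoidance, and — because occupancy sums to 100% —
peak occupancy is a dependent variable of the SD.

Two amplitude conventions are provided:

``normalized_2p``
    value_i = 100·g_i / Σ_j g_j with g_i = exp(−(T_i − T_peak)²/(2·SD²));
    predicted zone values sum to exactly 100, so only (T_peak, SD) are free.
``free_3p``
    value_i = A·g_i with a free amplitude A.  This is the default for
    fitting and nested F tests: with three free parameters per curve the
    residual degrees of freedom match pooled per-animal × per-zone fitting.

Fitting pools per-animal × per-zone points and minimizes least squares by a
coarse grid search with the amplitude solved in closed form (variable
projection), followed by local refinement.  The grid-then-refine strategy is
robust to the near-flat profiles produced by analgesia-like conditions,
which defeat pure gradient descent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .errors import DegenerateDataError

__all__ = [
    "GaussianPreferenceModel",
    "GaussianFitResult",
    "predict_occupancy",
    "fit_preference",
    "peak_occupancy_of",
    "TPEAK_GRID",
    "SD_GRID",
]

# coarse search box: T_peak spans the gradient; SD from sub-zone widths to
# wider-than-flat.  SD at the upper bound is reported as a flat preference.
TPEAK_MIN, TPEAK_MAX, TPEAK_STEP = 4.0, 58.0, 0.5
SD_MIN, SD_MAX, SD_STEP = 0.5, 40.0, 0.5
TPEAK_GRID = np.arange(TPEAK_MIN, TPEAK_MAX + 1e-9, TPEAK_STEP)
SD_GRID = np.arange(SD_MIN, SD_MAX + 1e-9, SD_STEP)


@dataclass(frozen=True)
class GaussianPreferenceModel:
    """Gaussian preference curve parameters."""

    t_peak_c: float
    sd_c: float
    amplitude_mode: str = "free_3p"
    amplitude: float | None = None

    def __post_init__(self) -> None:
        if self.sd_c <= 0:
            raise DegenerateDataError("sd_c must be > 0")
        if self.amplitude_mode not in ("normalized_2p", "free_3p"):
            raise ValueError(f"unknown amplitude_mode {self.amplitude_mode!r}")
        if self.amplitude_mode == "free_3p" and self.amplitude is None:
            raise ValueError("free_3p model requires an amplitude")

    @property
    def n_free_params(self) -> int:
        return 3 if self.amplitude_mode == "free_3p" else 2


@dataclass(frozen=True)
class GaussianFitResult:
    """Least-squares fit of the preference model to occupancy points."""

    model: GaussianPreferenceModel
    ss_residual: float
    df: int
    n_points: int
    peak_occupancy_percent: float
    converged: bool
    se_t_peak: float
    se_sd: float
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "amplitude_mode": self.model.amplitude_mode,
            "t_peak_c": self.model.t_peak_c,
            "se_t_peak": self.se_t_peak,
            "sd_c": self.model.sd_c,
            "se_sd": self.se_sd,
            "amplitude": self.model.amplitude,
            "peak_occupancy_percent": self.peak_occupancy_percent,
            "ss_residual": self.ss_residual,
            "df": self.df,
            "n_points": self.n_points,
            "converged": self.converged,
            "flags": list(self.flags),
        }


def _gauss(temps: np.ndarray, t_peak: float, sd: float) -> np.ndarray:
    d = temps - t_peak
    return np.exp(-(d * d) / (2.0 * sd * sd))


def predict_occupancy(
    model: GaussianPreferenceModel,
    zone_center_temps: Sequence[float],
    normalization_temps: Sequence[float] | None = None,
) -> np.ndarray:
    """Model-predicted percent occupancy at the given zone temperatures.

    In ``normalized_2p`` mode the normalization runs over
    ``normalization_temps`` (default: the zone temperatures themselves), so
    predictions at the full zone set sum to exactly 100.
    """
    temps = np.asarray(zone_center_temps, dtype=float)
    if temps.size == 0:
        raise DegenerateDataError("need at least one zone temperature")
    g = _gauss(temps, model.t_peak_c, model.sd_c)
    if model.amplitude_mode == "free_3p":
        return model.amplitude * g
    norm_t = temps if normalization_temps is None else np.asarray(
        normalization_temps, dtype=float
    )
    denom = _gauss(norm_t, model.t_peak_c, model.sd_c).sum()
    return 100.0 * g / denom


# ---------------------------------------------------------------------------
# profile sum-of-squares (amplitude projected out)


def profile_ss(
    t_peak: float,
    sd: float,
    temps: np.ndarray,
    percents: np.ndarray,
    amplitude_mode: str = "free_3p",
    norm_temps: np.ndarray | None = None,
) -> tuple[float, float]:
    """Residual SS at (t_peak, sd) with the amplitude at its conditional
    optimum (free_3p) or fixed by normalization (normalized_2p).

    Returns ``(ss, amplitude)``; for 2p the returned amplitude is the
    implied peak scaling ``100 / Σ g`` over the normalization temps.
    """
    g = _gauss(temps, t_peak, sd)
    if amplitude_mode == "free_3p":
        den = float(g @ g)
        if den == 0.0:
            return float(percents @ percents), 0.0
        amp = max(0.0, float(g @ percents) / den)
        ss = float(percents @ percents) - 2.0 * amp * float(g @ percents) + amp * amp * den
        return max(ss, 0.0), amp
    nt = temps if norm_temps is None else norm_temps
    denom = _gauss(nt, t_peak, sd).sum()
    pred = 100.0 * g / denom
    r = percents - pred
    return float(r @ r), 100.0 / float(denom)


def _grid_ss_matrix(
    temps: np.ndarray,
    percents: np.ndarray,
    amplitude_mode: str,
    norm_temps: np.ndarray,
) -> np.ndarray:
    """SS over the coarse grid, shape (len(SD_GRID), len(TPEAK_GRID)).

    Grid order (sd-major, then t_peak) makes ``argmin`` break exact ties
    toward smaller sd, then smaller t_peak.
    """
    diff = temps[None, :] - TPEAK_GRID[:, None]  # (n_tp, n_pts)
    d2 = diff * diff
    yy = float(percents @ percents)
    out = np.empty((len(SD_GRID), len(TPEAK_GRID)))
    if amplitude_mode == "normalized_2p":
        ndiff = norm_temps[None, :] - TPEAK_GRID[:, None]
        nd2 = ndiff * ndiff
    for i, sd in enumerate(SD_GRID):
        c = -1.0 / (2.0 * sd * sd)
        g = np.exp(d2 * c)  # (n_tp, n_pts)
        if amplitude_mode == "free_3p":
            gy = g @ percents
            gg = np.einsum("ij,ij->i", g, g)
            # gg underflows to 0 when the peak sits far outside the data
            safe = np.where(gg > 0.0, gg, 1.0)
            amp = np.where(gg > 0.0, np.clip(gy / safe, 0.0, None), 0.0)
            out[i] = yy - 2.0 * amp * gy + amp * amp * gg
        else:
            denom = np.maximum(np.exp(nd2 * c).sum(axis=1), 1e-300)
            pred = 100.0 * g / denom[:, None]
            r = percents[None, :] - pred
            out[i] = np.einsum("ij,ij->i", r, r)
    return out


def _standard_errors(
    t_peak: float,
    sd: float,
    amp: float,
    temps: np.ndarray,
    percents: np.ndarray,
    amplitude_mode: str,
    norm_temps: np.ndarray,
    ss: float,
    df: int,
) -> tuple[float, float]:
    """Gauss–Newton standard errors of (t_peak, sd) at the optimum."""
    if df < 1:
        return float("nan"), float("nan")

    if amplitude_mode == "free_3p":
        g = _gauss(temps, t_peak, sd)
        d = temps - t_peak
        cols = [
            g,  # d/d amplitude
            amp * g * d / (sd * sd),  # d/d t_peak
            amp * g * d * d / (sd**3),  # d/d sd
        ]
        J = np.column_stack(cols)
        k_tp, k_sd = 1, 2
    else:
        model0 = GaussianPreferenceModel(t_peak, sd, "normalized_2p")

        def pred(tp, s):
            return predict_occupancy(
                GaussianPreferenceModel(tp, s, "normalized_2p"), temps,
                normalization_temps=norm_temps,
            )

        h_tp, h_sd = 1e-5, 1e-5
        J = np.column_stack(
            [
                (pred(t_peak + h_tp, sd) - pred(t_peak - h_tp, sd)) / (2 * h_tp),
                (pred(t_peak, sd + h_sd) - pred(t_peak, sd - h_sd)) / (2 * h_sd),
            ]
        )
        k_tp, k_sd = 0, 1

    jtj = J.T @ J
    try:
        cov = (ss / df) * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        return float("nan"), float("nan")
    var = np.clip(np.diag(cov), 0.0, None)
    return float(np.sqrt(var[k_tp])), float(np.sqrt(var[k_sd]))


def fit_preference(
    temps: Sequence[float],
    percents: Sequence[float],
    amplitude_mode: str = "free_3p",
    zone_temps: Sequence[float] | None = None,
) -> GaussianFitResult:
    """Fit the Gaussian preference model to pooled occupancy points.

    Parameters
    ----------
    temps, percents
        Pooled per-animal × per-zone points (temperatures repeat across
        animals).
    amplitude_mode
        ``free_3p`` (default) or ``normalized_2p``.
    zone_temps
        Zone-center temperatures used for 2p normalization and for locating
        the peak-occupancy zone; defaults to the unique values of ``temps``.
    """
    T = np.asarray(temps, dtype=float)
    y = np.asarray(percents, dtype=float)
    if T.shape != y.shape:
        raise ValueError("temps and percents must have equal length")
    uniq = np.unique(T)
    if len(uniq) < 2:
        raise DegenerateDataError("temperatures must span >= 2 distinct values")
    n_params = 3 if amplitude_mode == "free_3p" else 2
    if len(T) < n_params + 1:
        raise DegenerateDataError(
            f"need at least {n_params + 1} points for a {n_params}-parameter fit"
        )
    norm_T = uniq if zone_temps is None else np.asarray(zone_temps, dtype=float)

    ssmat = _grid_ss_matrix(T, y, amplitude_mode, norm_T)
    i_sd, i_tp = np.unravel_index(int(np.argmin(ssmat)), ssmat.shape)
    tp0, sd0 = float(TPEAK_GRID[i_tp]), float(SD_GRID[i_sd])
    ss0 = float(ssmat[i_sd, i_tp])

    def objective(p):
        return profile_ss(p[0], p[1], T, y, amplitude_mode, norm_T)[0]

    res = optimize.minimize(
        objective,
        x0=[tp0, sd0],
        method="L-BFGS-B",
        bounds=[(TPEAK_MIN, TPEAK_MAX), (SD_MIN, SD_MAX)],
        options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
    )
    converged = bool(res.success)
    if res.fun <= ss0 + 1e-12:
        tp, sd = float(res.x[0]), float(res.x[1])
        ss = float(res.fun)
    else:  # refinement failed to improve; keep the grid optimum
        tp, sd, ss = tp0, sd0, ss0
        converged = False

    ss, amp = profile_ss(tp, sd, T, y, amplitude_mode, norm_T)

    flags: list[str] = []
    if sd >= SD_MAX - 1e-6:
        flags.append("flat_preference")
    if not converged:
        flags.append("refinement_not_converged")

    model = GaussianPreferenceModel(
        t_peak_c=tp,
        sd_c=sd,
        amplitude_mode=amplitude_mode,
        amplitude=amp if amplitude_mode == "free_3p" else None,
    )
    df = len(T) - n_params
    preds = predict_occupancy(model, norm_T, normalization_temps=norm_T)
    nearest = int(np.argmin(np.abs(norm_T - tp)))
    se_tp, se_sd = _standard_errors(
        tp, sd, amp, T, y, amplitude_mode, norm_T, ss, df
    )
    return GaussianFitResult(
        model=model,
        ss_residual=ss,
        df=df,
        n_points=len(T),
        peak_occupancy_percent=float(preds[nearest]),
        converged=converged,
        se_t_peak=se_tp,
        se_sd=se_sd,
        flags=tuple(flags),
    )


def peak_occupancy_of(
    sd_c: float,
    zone_center_temps: Sequence[float],
    t_peak_c: float,
) -> float:
    """Maximum zone occupancy implied by a normalized (2p) Gaussian of the
    given width — the sense in which peak occupancy depends on the SD."""
    model = GaussianPreferenceModel(t_peak_c, sd_c, "normalized_2p")
    return float(predict_occupancy(model, zone_center_temps).max())
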