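"""Statistical comparisons and study planning for preference fits.

Group comparisons of fitted Gaussian parameters use the extra sum-of-squares
F test on nested fits of the pooled occupancy points: the null model shares
the parameter under test between groups (all other parameters separate), the
alternative fits each group freely, and

    F = ((SS_null − SS_alt)/(df_null − df_alt)) / (SS_alt/df_alt)

is referred to the F distribution with (df_null − df_alt, df_alt) degrees of
freedom.  Simple group summaries (distance traveled, resting time) are
compared with Welch or paired t tests.  Planning uses Cohen's d with the
pooled residual SD, σ = sqrt((SS_a + SS_b)/(DFd_a + DFd_b)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from . import preference
from .errors import DegenerateDataError, UndefinedTestError
from .preference import (
    SD_GRID,
    SD_MAX,
    SD_MIN,
    TPEAK_GRID,
    TPEAK_MAX,
    TPEAK_MIN,
    GaussianFitResult,
    fit_preference,
    profile_ss,
)

__all__ = [
    "NestedFitComparison",
    "TTestResult",
    "EffectSize",
    "PowerSpec",
    "extra_ss_f_test",
    "compare_preference",
    "welch_t_test",
    "paired_t_test",
    "cohens_d",
    "sample_size_per_group",
]


@dataclass(frozen=True)
class NestedFitComparison:
    """Extra sum-of-squares F test between nested least-squares fits."""

    ss_null: float
    df_null: int
    ss_alt: float
    df_alt: int
    f_stat: float
    df_numerator: int
    df_denominator: int
    p_value: float
    parameter_tested: str | None = None
    group_fits: tuple[GaussianFitResult, ...] = ()

    def to_dict(self) -> dict:
        return {
            "parameter_tested": self.parameter_tested,
            "f_stat": self.f_stat,
            "df_num": self.df_numerator,
            "df_den": self.df_denominator,
            "p_value": self.p_value,
            "ss_null": self.ss_null,
            "df_null": self.df_null,
            "ss_alt": self.ss_alt,
            "df_alt": self.df_alt,
            "group_fits": [f.to_dict() for f in self.group_fits],
        }


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    p_value: float
    mean_difference: float
    test_kind: str


@dataclass(frozen=True)
class EffectSize:
    """Cohen's d with the pooled residual SD in the denominator."""

    delta_mu: float
    pooled_sigma: float
    d: float


@dataclass(frozen=True)
class PowerSpec:
    alpha: float = 0.05
    power: float = 0.80
    method: str = "normal_approx"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.method not in ("normal_approx", "noncentral_t"):
            raise ValueError(f"unknown method {self.method!r}")


# ---------------------------------------------------------------------------
# Nested F test


def extra_ss_f_test(
    ss_null: float,
    df_null: int,
    ss_alt: float,
    df_alt: int,
    parameter_tested: str | None = None,
    group_fits: Sequence[GaussianFitResult] = (),
) -> NestedFitComparison:
    """F test from the residual SS and df of two nested fits."""
    if df_null <= df_alt:
        raise DegenerateDataError(
            "models are not nested: df_null must exceed df_alt"
        )
    if ss_alt < 0 or ss_null < 0:
        raise ValueError("sums of squares must be non-negative")
    if ss_alt == 0:
        raise DegenerateDataError(
            "alternative fit is exact (SS = 0); F statistic undefined"
        )
    # numerical round-off in independent optimizations can leave
    # ss_null a hair below ss_alt; clamp the difference at 0
    extra = max(ss_null - ss_alt, 0.0)
    df_num = df_null - df_alt
    f_stat = (extra / df_num) / (ss_alt / df_alt)
    p = float(stats.f.sf(f_stat, df_num, df_alt))
    return NestedFitComparison(
        ss_null=ss_null,
        df_null=df_null,
        ss_alt=ss_alt,
        df_alt=df_alt,
        f_stat=float(f_stat),
        df_numerator=df_num,
        df_denominator=df_alt,
        p_value=p,
        parameter_tested=parameter_tested,
        group_fits=tuple(group_fits),
    )


def _shared_parameter_fit(
    T_a: np.ndarray,
    y_a: np.ndarray,
    T_b: np.ndarray,
    y_b: np.ndarray,
    parameter: str,
    amplitude_mode: str,
    norm_a: np.ndarray,
    norm_b: np.ndarray,
) -> tuple[float, float, float, float]:
    """Constrained fit sharing one parameter between the two groups.

    Returns ``(ss_total, shared_value, free_a, free_b)`` where ``free_*``
    are the groups' values of the unconstrained shape parameter.
    """
    # coarse scan: SS matrices (sd, tp) per group, then minimize the sum
    # along the shared axis with the other shape parameter free per group
    mat_a = preference._grid_ss_matrix(T_a, y_a, amplitude_mode, norm_a)
    mat_b = preference._grid_ss_matrix(T_b, y_b, amplitude_mode, norm_b)
    if parameter == "t_peak":
        shared_grid, axis = TPEAK_GRID, 0  # minimize over sd per tp
        lo, hi, flo, fhi = TPEAK_MIN, TPEAK_MAX, SD_MIN, SD_MAX
    elif parameter == "sd":
        shared_grid, axis = SD_GRID, 1  # minimize over tp per sd
        lo, hi, flo, fhi = SD_MIN, SD_MAX, TPEAK_MIN, TPEAK_MAX
    else:
        raise ValueError("parameter must be 't_peak' or 'sd'")

    prof_a = mat_a.min(axis=axis)
    prof_b = mat_b.min(axis=axis)
    arg_a = mat_a.argmin(axis=axis)
    arg_b = mat_b.argmin(axis=axis)
    free_grid = SD_GRID if parameter == "t_peak" else TPEAK_GRID
    i_shared = int(np.argmin(prof_a + prof_b))
    shared0 = float(shared_grid[i_shared])
    free_a0 = float(free_grid[arg_a[i_shared]])
    free_b0 = float(free_grid[arg_b[i_shared]])

    def unpack(p):
        if parameter == "t_peak":
            return (p[0], p[1]), (p[0], p[2])
        return (p[1], p[0]), (p[2], p[0])

    def objective(p):
        (tp_a, sd_a), (tp_b, sd_b) = unpack(p)
        return (
            profile_ss(tp_a, sd_a, T_a, y_a, amplitude_mode, norm_a)[0]
            + profile_ss(tp_b, sd_b, T_b, y_b, amplitude_mode, norm_b)[0]
        )

    res = optimize.minimize(
        objective,
        x0=[shared0, free_a0, free_b0],
        method="L-BFGS-B",
        bounds=[(lo, hi), (flo, fhi), (flo, fhi)],
        options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
    )
    ss0 = float(prof_a[i_shared] + prof_b[i_shared])
    if res.fun <= ss0 + 1e-12:
        return float(res.fun), float(res.x[0]), float(res.x[1]), float(res.x[2])
    return ss0, shared0, free_a0, free_b0


def compare_preference(
    temps_a: Sequence[float],
    percents_a: Sequence[float],
    temps_b: Sequence[float],
    percents_b: Sequence[float],
    parameter: str = "t_peak",
    amplitude_mode: str = "free_3p",
    zone_temps: Sequence[float] | None = None,
) -> NestedFitComparison:
    """Nested F test for a group difference in one Gaussian parameter.

    The alternative model fits each group's pooled points freely; the null
    model constrains ``parameter`` (``"t_peak"`` or ``"sd"``) to a shared
    value while the remaining shape parameter (and amplitude, in 3p mode)
    stay group-specific.
    """
    T_a = np.asarray(temps_a, dtype=float)
    y_a = np.asarray(percents_a, dtype=float)
    T_b = np.asarray(temps_b, dtype=float)
    y_b = np.asarray(percents_b, dtype=float)
    fit_a = fit_preference(T_a, y_a, amplitude_mode, zone_temps)
    fit_b = fit_preference(T_b, y_b, amplitude_mode, zone_temps)
    ss_alt = fit_a.ss_residual + fit_b.ss_residual
    df_alt = fit_a.df + fit_b.df

    norm_a = np.unique(T_a) if zone_temps is None else np.asarray(zone_temps, float)
    norm_b = np.unique(T_b) if zone_temps is None else np.asarray(zone_temps, float)
    ss_null, *_ = _shared_parameter_fit(
        T_a, y_a, T_b, y_b, parameter, amplitude_mode, norm_a, norm_b
    )
    df_null = df_alt + 1  # one parameter shared
    return extra_ss_f_test(
        ss_null,
        df_null,
        ss_alt,
        df_alt,
        parameter_tested=parameter,
        group_fits=(fit_a, fit_b),
    )


# ---------------------------------------------------------------------------
# t tests


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Two-tailed heteroscedastic (Welch) t test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise UndefinedTestError("each sample needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0:
        raise UndefinedTestError("both samples have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        mean_difference=float(a.mean() - b.mean()),
        test_kind="welch",
    )


def paired_t_test(before: Sequence[float], after: Sequence[float]) -> TTestResult:
    """Two-tailed paired t test on per-animal differences."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if len(before) != len(after):
        raise ValueError("paired samples must have equal length")
    if len(before) < 2:
        raise UndefinedTestError("paired test needs n >= 2 pairs")
    if np.var(after - before) == 0:
        raise UndefinedTestError("paired differences have zero variance")
    res = stats.ttest_rel(after, before)
    return TTestResult(
        statistic=float(res.statistic),
        df=float(len(before) - 1),
        p_value=float(res.pvalue),
        mean_difference=float((after - before).mean()),
        test_kind="paired",
    )


# ---------------------------------------------------------------------------
# effect size and sample size


def cohens_d(
    delta_mu: float,
    ss_a: float,
    dfd_a: float,
    ss_b: float,
    dfd_b: float,
) -> EffectSize:
    """Cohen's d with pooled residual SD,
    σ = sqrt((SS_a + SS_b)/(DFd_a + DFd_b))."""
    if ss_a < 0 or ss_b < 0:
        raise ValueError("sums of squares must be non-negative")
    if dfd_a + dfd_b <= 0:
        raise DegenerateDataError("total residual df must be positive")
    pooled = math.sqrt((ss_a + ss_b) / (dfd_a + dfd_b))
    if pooled == 0:
        raise DegenerateDataError("pooled variance is zero; d undefined")
    return EffectSize(delta_mu=delta_mu, pooled_sigma=pooled, d=delta_mu / pooled)


def _power_noncentral_t(n: int, d: float, alpha: float) -> float:
    df = 2 * n - 2
    nc = abs(d) * math.sqrt(n / 2.0)
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(t_crit, df, nc) + stats.nct.cdf(-t_crit, df, nc))


def sample_size_per_group(d: float, spec: PowerSpec = PowerSpec()) -> int:
    """Minimal per-group n for a two-sided two-sample comparison.

    Default ``normal_approx``: ``n = ceil(2·(z_{1−α/2} + z_{power})² / d²)``.
    ``noncentral_t``: smallest n whose exact two-sample noncentral-t power
    reaches the target (always ≥ the normal approximation).  Results below
    2 are floored at 2.
    """
    if d == 0:
        raise DegenerateDataError("cannot size a study for a zero effect")
    if spec.method == "normal_approx":
        z_a = stats.norm.ppf(1 - spec.alpha / 2)
        z_b = stats.norm.ppf(spec.power)
        n = math.ceil(2.0 * (z_a + z_b) ** 2 / d**2)
    else:
        n = 2
        while _power_noncentral_t(n, d, spec.alpha) < spec.power:
            n += 1
            if n > 10**6:
                raise RuntimeError("sample size search did not terminate")
    return max(n, 2)
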