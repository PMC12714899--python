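# Methods

## The assay and its coordinate conventions

A corridor of length L = 137 cm carries a linear floor-temperature
gradient. We place x = 0 at the cold end so the calibration intercept is
the cold-end temperature; the nominal calibration is the endpoint line
(4 °C at x = 0, 58 °C at x = L, slope 54/137 ≈ 0.394 °C/cm), and a fitted
calibration (ordinary least squares through thermocouple readings at known
positions) overrides it when measurements are supplied. Outputs label
which mode was used. R² of a zero-variance calibration is defined as 0,
never NaN. The corridor is partitioned into n = 14 equal zones numbered
cold→hot; zone bins are half-open `[lo, hi)` with the hot boundary closed,
and zone indices are computed as `floor(x·n/L) + 1` so exact zone
boundaries are classified exactly in floating point.

Transverse (y) temperature variation is ignored: the gradient is 1-D along
the corridor, and the animal is treated as the point its tracker reports
(its center of mass).

## Preprocessing

Recordings are analyzed at the camera rate (default 15 frames/s). The
first 30 s are excluded as exploration-dominated and the remainder is
clipped to a 600-s analysis window, so the standard assay contributes
exactly `floor((600 − 30)·15) = 8550` frames per animal. Timestamps are
re-zeroed to the window start. Irregular timestamps are snapped to the
nominal frame grid by nearest-sample lookup; tracking dropouts (empty
cells) are forward-filled up to 1 s and longer gaps are dropped with a
per-animal warning.

Median smoothing of position (window 5 frames, edge-replicated) is applied
inside the activity metrics, where tracker jitter otherwise inflates path
length, and is off by default for occupancy, which is robust to sub-zone
jitter. The filter's edge replication keeps smoothed positions inside the
range of the raw ones and makes distance invariant to appending stationary
frames.

## Occupancy

Occupancy is frame-counting: percent of analyzed frames per zone over a
half-open time window, with the zone-center temperature as abscissa.
Profiles therefore sum to 100 exactly, group summaries are mean ± SEM
(sample SD/√n; a single-animal group reports SEM 0 with a warning), and
occupancy over a window equals the frame-weighted average of occupancy
over any partition of it. Sliding windows `[k·step, k·step + W)` support
both overlapping (step < W) and disjoint (step = W) designs; the last
window is clipped to the track end.

## Gaussian preference model and fitting

Occupancy vs zone temperature is modeled as a Gaussian with center
`T_peak` and width `SD`. Two amplitude conventions:

- `normalized_2p`: predictions are `100·g_i/Σ_j g_j` over the zone set, so
  they sum to exactly 100 and peak occupancy is a deterministic function
  of the SD (the conceptual readout: narrower preference ⇒ higher peak).
- `free_3p` (default for fitting and F tests): `A·g_i` with free
  amplitude. Pooled per-animal × per-zone fitting with three parameters
  per curve is what makes the nested-test degrees of freedom come out as
  `n_points − 3` per group (e.g. 12 animals × 14 zones × 2 curves gives a
  denominator df of 330 for a one-parameter comparison), which is the df
  bookkeeping this package reports.

Fitting is least squares by **variable projection**: for each candidate
`(T_peak, SD)` the amplitude has the closed form `Σg·y/Σg²` (clamped at
0), so the search runs over a 2-D profile surface. A coarse grid
(`T_peak` over 4–58 °C and `SD` over 0.5–40 °C, both at 0.5 °C steps) is
scanned first, then the best cell is refined with bounded L-BFGS-B. The
grid stage is what keeps near-flat profiles (analgesia-like conditions)
from trapping a local optimizer: such data report `SD` at the 40 °C upper
bound with a `flat_preference` flag rather than a spurious sharp peak.
Exact grid ties break toward smaller `SD`, then smaller `T_peak`
(deterministic output). Standard errors come from the Gauss–Newton
approximation at the optimum (analytic Jacobian in 3p mode, central
differences in 2p mode); `df ≥ 1` is required for a reported fit. Fits
need at least `n_params + 1` points spanning ≥2 distinct temperatures.

## Group comparison

The extra sum-of-squares F test compares nested fits of the same pooled
points: the alternative fits each group freely; the null shares exactly
the parameter under test (`t_peak` or `sd`) while the other shape
parameter and the amplitudes stay group-specific, giving a one-parameter
numerator. The constrained fit reuses the grid machinery (scan the shared
parameter's grid, minimizing the free parameter per group, then refine the
3-D problem jointly). Tiny negative `SS_null − SS_alt` values from
independent optimizations are clamped to 0. Tail probabilities come from
the F distribution (regularized incomplete beta via scipy); p-values are
reported in full precision and no multiple-testing correction is applied —
reports list every test run so users can apply their own.

**Known limitation.** Pooling per-animal × per-zone points treats the 14
values from one animal as independent observations. They are not: they
sum to 100 and the underlying positions are autocorrelated, so on
simulated tracked cohorts the pooled F test over-rejects under the null
(a dedicated test keeps this visible). The test's type-I calibration is
therefore validated under its own error model — identical groups drawn
from the preference curve with independent point noise — where the
measured rejection rate at α = 0.05 is ~0.04–0.05. Per-animal
random-effect models are out of scope; comparisons of per-animal scalar
summaries (Welch/paired t) are the conservative alternative when
within-animal correlation is a concern.

Welch's t test (heteroscedastic, two-tailed, Welch–Satterthwaite df) and
the paired t test require n ≥ 2 per sample and at least one non-zero
variance; both-zero-variance inputs raise an error rather than returning a
degenerate statistic.

## Activity metrics

Distance is the summed frame-to-frame displacement of smoothed positions,
in meters. Immobility bouts are maximal runs of frames with smoothed speed
below 0.5 cm/s (a configuration key — video trackers differ in their
sensitivity, and no displacement criterion is canonical) lasting strictly
more than 3.0 s; a single supra-threshold frame inside a run is bridged
(1-frame gap tolerance, also configurable). Each bout is assigned the zone
of its mean position; resting percent decomposes exactly into its per-zone
vector.

## The simulator

`simulate_track` is a discrete-time Ornstein–Uhlenbeck process at
dt = 1/fps: while moving,
`x ← x + k·(x_pref − x)·dt + σ_w·√dt·ξ`, reflected into `[0, L]`, with
`x_pref` the preferred temperature mapped through the calibration and
`σ_w = (SD_pref/slope)·√(2k)` so the unreflected stationary law is
Gaussian with exactly the requested temperature-domain SD. Reflection
truncates rather than distorts that law (zero-flux boundaries renormalize
the density on the corridor), so the free amplitude of the 3p fit absorbs
the truncation and parameter recovery stays well-posed. The OU family was
chosen precisely because its stationary law is the model the analysis
fits: recovery of `(T_peak, SD)` from simulated cohorts is then a
meaningful end-to-end test of the pipeline rather than a tautology about
binned noise.

Rest bouts: while moving, a bout starts with per-second hazard
`rest_hazard·exp(−(T(x) − T_pref)²/(2·SD_pref²))` — animals settle where
they are comfortable, which reproduces the observation that long rests
follow the occupancy distribution. Bout durations are exponential
(mean `rest_mean_s`) and freeze the position. Defaults k = 0.2 /s,
hazard 0.05 /s, mean 6 s give naive cohorts roughly 20% resting in 10
min; the preference weighting makes the realized occupancy slightly
narrower than the pure OU law (a few percent in SD at these defaults),
which is inside the recovery tolerances used in testing.

`locomotion_scale` s rescales the process clock — σ_w by s and k by s² —
so travel speed (and hence distance traveled) changes while the
stationary preference distribution is untouched. A σ-only scaling would
change the stationary SD and corrupt the very quantity the assay
estimates, so the clock rescaling is the package's definition of the
knob. With `attraction_rate = 0` the σ_w formula degenerates, and the
process falls back to reflected Brownian motion with magnitude
`baseline_diffusion_cm_per_sqrt_s` (default 18 cm/√s, the σ_w scale of
the naive presets), whose stationary law is uniform — the no-preference
control.

Per-animal randomness derives from `SeedSequence([seed, animal_index])`,
so cohorts are bit-reproducible and reordering animals never changes a
path.

### Condition presets

| preset | T_pref (°C) | SD (°C) | locomotion | rest hazard/mean | emulates |
|---|---|---|---|---|---|
| naive_male | 30.4 | 11.6 | 1.0 | 0.05 /s, 6 s | naive male preference |
| naive_female | 32.2 | 13.8 | 1.0 | 0.05 /s, 6 s | warmer, broader preference |
| cfa | 36.6 | 6.1 | 0.6 | 0.10 /s, 8 s | inflamed paw: warm-shifted, narrowed, hypolocomotive, more resting |
| naive_morphine | — (flat) | 40 (bound) | 1.5 | 0.01 /s, 3 s | analgesia: flattened preference, hyperlocomotion |
| cfa_morphine | — (flat) | 40 (bound) | 2.0 | 0.01 /s, 3 s | strongest hyperlocomotion |
| no_gradient | — | — | 1.0 | 0.05 /s, 6 s | corner-seeking U-shape on a uniform floor (qualitative only) |

The Gaussian presets' centers and widths are the anchors the recovery
tests target; the morphine presets are phenomenological (flatness plus
speed, not pharmacokinetics), and `no_gradient` adds a weak drift toward
the nearest end to caricature corner-seeking — it is illustrative, not
validated.

### What the simulator does not emulate

Real tracks are not diffusions: mice move in directed runs with pauses,
so at 15 fps the OU path accumulates far more frame-to-frame displacement
than a real mouse (simulated "distances traveled" are several-fold larger
than published animal values). Distance comparisons between presets are
therefore meaningful as orderings, not magnitudes. Likewise absent:
2-D wall-following, grooming microstructure, thermal physiology, sex-cycle
variability, and habituation drift within a session. Passing recovery
tests show the *analysis* is correct and well-calibrated for data whose
stationary structure matches its model — they do not certify tracker
artifacts or non-stationary behavior in real recordings.

## Planning computations

Cohen's d uses the pooled residual SD
`σ = sqrt((SS_a + SS_b)/(DFd_a + DFd_b))`. The default per-group size is
the two-sample normal approximation `n = ⌈2(z_{1−α/2} + z_{power})²/d²⌉`
(α two-sided), floored at 2; at σ = 1.2 °C it gives n = 11 for a 1.5 °C
shift and n = 6 for a 2.0 °C shift. The exact noncentral-t search is
available (`method="noncentral_t"`) and returns values one animal larger
at these effect sizes; the approximation is the default because it is the
convention this assay's planning numbers follow. Note the caveat inherited
from using a pooled *residual* σ: between-animal variance is not in the
denominator, so d can be optimistic — the exact method and larger ns are
recommended when animals are expensive.

## Problem sizes used in validation

Simulation-backed checks use cohorts sized for stable Monte-Carlo
behavior at interactive runtimes: recovery uses 12 animals × 600 s × 10
seeds per preset; the uniform-occupancy benchmark integrates a single
8-h no-drift track; F-test calibration uses 1000 replicates of 6 × 14
iid-noise points per group; stationarity χ² checks subsample frames 20 s
apart (≈4 relaxation times) so the goodness-of-fit test sees
near-independent draws.
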