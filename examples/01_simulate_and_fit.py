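"""Simulate a naive-male cohort and fit its temperature preference.

Builds a 12-animal, 10-minute cohort from the naive_male preset, converts
each preprocessed track into a 14-zone occupancy profile, pools the
per-animal points, and fits the Gaussian preference model.  T_peak is the
most preferred temperature; the SD measures how sharply the animals avoid
temperatures away from it; peak occupancy is the fraction of time spent in
the best zone.
"""

from thermopref import (
    fit_preference,
    occupancy_profile,
    pooled_points,
    preprocess,
    simulate_cohort,
)

cohort = simulate_cohort("naive_male", n_animals=12, seed=1)
profiles = [
    occupancy_profile(preprocess(t), cohort.arena, cohort.calibration)
    for t in cohort.tracks
]
fit = fit_preference(*pooled_points(profiles))

print(f"n animals          : {len(cohort)}")
print(f"points fitted      : {fit.n_points} (12 animals x 14 zones)")
print(f"T_peak             : {fit.model.t_peak_c:.1f} +/- {fit.se_t_peak:.1f} C")
print(f"SD                 : {fit.model.sd_c:.1f} +/- {fit.se_sd:.1f} C")
print(f"peak occupancy     : {fit.peak_occupancy_percent:.1f} %")
print(f"residual SS (df)   : {fit.ss_residual:.1f} ({fit.df})")
print()
print("The fitted center should sit near the preset's 30.4 C preference;")
print("a flat 7.1 %/zone profile would instead signal no thermal preference.")
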