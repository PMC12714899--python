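"""Locomotion and resting structure of an inflamed vs a naive cohort.

Distance traveled and >3-s immobility bouts are the assay's activity
readouts: inflammation reduces locomotion and concentrates long rests in
the preferred (comfortable) zones.
"""

import numpy as np

from thermopref import (
    detect_immobility_bouts,
    distance_traveled,
    occupancy_profile,
    preprocess,
    resting_summary,
    simulate_cohort,
)

for name in ("naive_female", "cfa"):
    cohort = simulate_cohort(name, n_animals=6, seed=4)
    dist, rest, rest_zone, occ_zone = [], [], [], []
    for track in cohort.tracks:
        t = preprocess(track)
        bouts = detect_immobility_bouts(t, arena=cohort.arena)
        summary = resting_summary(t, bouts, cohort.arena)
        dist.append(summary.distance_m)
        rest.append(summary.resting_percent)
        rest_zone.append(int(np.argmax(summary.resting_percent_by_zone)) + 1)
        occ_zone.append(
            int(np.argmax(occupancy_profile(t, cohort.arena).percent_by_zone)) + 1
        )
    print(f"{name}")
    print(f"  distance traveled : {np.mean(dist):.1f} +/- {np.std(dist):.1f} m / 9.5 min")
    print(f"  resting (>3 s)    : {np.mean(rest):.1f} % of frames")
    print(f"  modal rest zone   : {rest_zone}  (modal occupancy zone {occ_zone})")

print()
print("The inflamed (cfa) cohort travels less and rests more than the naive")
print("one, and its long rests cluster in the same zones it occupies most.")
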