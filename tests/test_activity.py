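"""Distance traveled, immobility bouts, resting summaries."""

import numpy as np
import pytest

from thermopref import (
    AnimalTrack,
    detect_immobility_bouts,
    distance_traveled,
    resting_summary,
)
from thermopref.errors import DegenerateDataError


def track_from_x(x, fps=15.0):
    x = np.asarray(x, dtype=float)
    return AnimalTrack("m1", np.arange(len(x)) / fps, x, fps=fps)


class TestDistance:
    def test_stationary_zero(self):
        assert distance_traveled(track_from_x(np.full(100, 50.0))) == 0.0

    def test_single_traverse(self):
        x = np.linspace(0, 137, 600)
        assert distance_traveled(track_from_x(x), smooth_window=0) == pytest.approx(
            1.37
        )

    def test_there_and_back(self):
        x = np.concatenate([np.linspace(0, 137, 300), np.linspace(137, 0, 300)])
        assert distance_traveled(track_from_x(x), smooth_window=0) == pytest.approx(
            2.74
        )

    def test_too_few_frames(self):
        with pytest.raises(DegenerateDataError):
            distance_traveled(track_from_x([50.0]))

    def test_invariant_to_time_rezeroing_and_stationary_padding(self):
        x = np.linspace(10, 90, 450)
        base = distance_traveled(track_from_x(x))
        shifted = AnimalTrack("m1", np.arange(450) / 15.0 + 300.0, x, fps=15.0)
        assert distance_traveled(shifted) == pytest.approx(base)
        padded = np.concatenate([x, np.full(100, x[-1])])
        assert distance_traveled(track_from_x(padded)) == pytest.approx(base)

    def test_smoothing_reduces_jitter_inflation(self, rng):
        x = np.clip(60 + rng.normal(0, 0.3, 9000), 0, 137)  # pure jitter
        raw = distance_traveled(track_from_x(x), smooth_window=0)
        smoothed = distance_traveled(track_from_x(x), smooth_window=5)
        assert smoothed < raw


class TestImmobilityBouts:
    def test_entirely_stationary_window(self):
        track = track_from_x(np.full(8550, 30.0))
        bouts = detect_immobility_bouts(track)
        assert len(bouts) == 1
        assert bouts[0].duration_s == pytest.approx(570.0)
        summary = resting_summary(track, bouts)
        assert summary.resting_percent == pytest.approx(100.0)

    def test_constant_fast_motion_has_no_bouts(self):
        x = (np.arange(3000) * 5.0 / 15.0) % 137  # 5 cm/s sawtooth
        bouts = detect_immobility_bouts(track_from_x(x), smooth_window=0)
        assert bouts == []

    def test_embedded_stop_detected_once(self):
        moving1 = 30 + np.arange(150) * 2.0 / 15.0
        stop = np.full(75, moving1[-1])  # 5 s still
        moving2 = stop[-1] + np.arange(150) * 2.0 / 15.0
        track = track_from_x(np.concatenate([moving1, stop, moving2]))
        bouts = detect_immobility_bouts(track, smooth_window=0)
        assert len(bouts) == 1
        assert bouts[0].duration_s == pytest.approx(5.0, abs=1 / 15 * 2)

    def test_durations_strictly_exceed_minimum(self):
        moving = 30 + np.arange(150) * 2.0 / 15.0
        exactly_3s = np.full(45, moving[-1])
        track = track_from_x(np.concatenate([moving, exactly_3s, moving[::-1] + 20]))
        assert detect_immobility_bouts(track, smooth_window=0, min_bout_s=3.0) == []

    def test_single_frame_gap_does_not_split(self):
        # a single step between two long stills gives one supra-threshold
        # frame, which the 1-frame gap tolerance bridges
        x = np.concatenate([np.full(75, 50.0), np.full(75, 51.0)])
        bouts = detect_immobility_bouts(track_from_x(x), smooth_window=0)
        assert len(bouts) == 1
        assert bouts[0].duration_s == pytest.approx(10.0, abs=0.2)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            detect_immobility_bouts(track_from_x(np.zeros(10)), speed_threshold_cm_s=0)


class TestRestingSummary:
    def test_no_bouts(self):
        x = (np.arange(3000) * 5.0 / 15.0) % 137
        track = track_from_x(x)
        summary = resting_summary(track, [])
        assert summary.resting_percent == 0.0
        assert summary.resting_percent_by_zone.sum() == 0.0

    def test_per_zone_decomposition_conserves_total(self):
        moving = np.linspace(5, 100, 300)
        stop = np.full(120, 100.0)
        track = track_from_x(np.concatenate([moving, stop, moving[::-1]]))
        bouts = detect_immobility_bouts(track, smooth_window=0)
        summary = resting_summary(track, bouts)
        assert summary.resting_percent_by_zone.sum() == pytest.approx(
            summary.resting_percent, abs=1e-9
        )
        assert 0 < summary.resting_percent < 100

    def test_single_zone_bout_attribution(self):
        track = track_from_x(np.full(900, 30.0))  # zone 4 throughout
        bouts = detect_immobility_bouts(track)
        summary = resting_summary(track, bouts)
        assert summary.resting_percent_by_zone[3] == pytest.approx(
            summary.resting_percent
        )

    def test_resting_concentrates_in_preferred_zones(self):
        # rest hazard is weighted toward the preferred temperature, so the
        # modal resting zone should match the modal occupancy zone
        from thermopref import occupancy_profile, simulate_cohort, preprocess

        hits = 0
        for seed in range(10):
            cohort = simulate_cohort("naive_male", n_animals=4, seed=seed)
            rest = np.zeros(14)
            occ = np.zeros(14)
            for t in cohort.tracks:
                p = preprocess(t)
                occ += occupancy_profile(p, cohort.arena, cohort.calibration).percent_by_zone
                bouts = detect_immobility_bouts(p)
                rest += resting_summary(p, bouts).resting_percent_by_zone
            hits += abs(int(np.argmax(rest)) - int(np.argmax(occ))) <= 1
        assert hits >= 8
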