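"""Nested F tests, t tests, effect size and sample-size planning."""

import numpy as np
import pytest
from scipy import stats

from thermopref import (
    GaussianPreferenceModel,
    PowerSpec,
    cohens_d,
    compare_preference,
    extra_ss_f_test,
    paired_t_test,
    predict_occupancy,
    sample_size_per_group,
    simulate_cohort,
    welch_t_test,
)
from thermopref import occupancy_profile, pooled_points, preprocess
from thermopref.errors import DegenerateDataError, UndefinedTestError


class TestExtraSSFTest:
    def test_formula_against_distribution_oracle(self):
        res = extra_ss_f_test(12.0, 21, 10.0, 20)
        assert res.f_stat == pytest.approx(4.0)
        assert res.p_value == pytest.approx(stats.f.sf(4.0, 1, 20))
        assert res.p_value == pytest.approx(0.0593, abs=5e-4)

    def test_equal_ss_gives_f_zero_p_one(self):
        res = extra_ss_f_test(10.0, 21, 10.0, 20)
        assert res.f_stat == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_non_nested_inputs_rejected(self):
        with pytest.raises(DegenerateDataError):
            extra_ss_f_test(10.0, 20, 12.0, 21)
        with pytest.raises(DegenerateDataError):
            extra_ss_f_test(10.0, 20, 0.0, 19)

    def test_identical_groups_not_significant(self, zone_temps, rng):
        mu = predict_occupancy(
            GaussianPreferenceModel(30.4, 11.6, "normalized_2p"), zone_temps
        )
        y = np.concatenate([mu + rng.normal(0, 2, 14) for _ in range(6)])
        T = np.tile(zone_temps, 6)
        res = compare_preference(T, y, T, y.copy(), parameter="t_peak")
        assert res.f_stat == pytest.approx(0.0, abs=1e-4)
        assert res.p_value == pytest.approx(1.0, abs=1e-4)

    def test_nested_ss_ordering_holds_on_fits(self, zone_temps, rng):
        for parameter in ("t_peak", "sd"):
            ya = np.concatenate(
                [
                    predict_occupancy(
                        GaussianPreferenceModel(30.0, 10.0, "normalized_2p"),
                        zone_temps,
                    )
                    + rng.normal(0, 2, 14)
                    for _ in range(4)
                ]
            )
            yb = np.concatenate(
                [
                    predict_occupancy(
                        GaussianPreferenceModel(33.0, 13.0, "normalized_2p"),
                        zone_temps,
                    )
                    + rng.normal(0, 2, 14)
                    for _ in range(4)
                ]
            )
            T = np.tile(zone_temps, 4)
            res = compare_preference(T, ya, T, yb, parameter=parameter)
            assert res.ss_null >= res.ss_alt - 1e-9
            assert res.df_null == res.df_alt + 1

    def test_shared_fit_matches_grid_oracle_on_toy_data(self, zone_temps, rng):
        # independent oracle: exhaustive fine-grid search for the shared
        # t_peak minimizing the summed group SS
        from thermopref.preference import profile_ss

        mu_a = predict_occupancy(
            GaussianPreferenceModel(30.0, 10.0, "normalized_2p"), zone_temps
        )
        mu_b = predict_occupancy(
            GaussianPreferenceModel(32.0, 10.0, "normalized_2p"), zone_temps
        )
        ya = mu_a + rng.normal(0, 1.5, 14)
        yb = mu_b + rng.normal(0, 1.5, 14)
        res = compare_preference(zone_temps, ya, zone_temps, yb, parameter="t_peak")

        def null_ss(tp):
            best = np.inf
            for sd_a in np.arange(5, 20, 0.05):
                best_a = profile_ss(tp, sd_a, zone_temps, ya, "free_3p")[0]
                best = min(best, best_a)
            best_b = np.inf
            for sd_b in np.arange(5, 20, 0.05):
                best_b = min(best_b, profile_ss(tp, sd_b, zone_temps, yb, "free_3p")[0])
            return best + best_b

        grid = np.arange(28.0, 34.0, 0.02)
        oracle = min(null_ss(tp) for tp in grid)
        f_oracle = ((oracle - res.ss_alt) / 1) / (res.ss_alt / res.df_alt)
        assert res.ss_null <= oracle + 1e-6
        assert res.f_stat == pytest.approx(f_oracle, abs=1e-2)

    def test_pooled_points_overreject_with_within_animal_correlation(self):
        # documented limitation: pooled per-animal x per-zone points violate
        # the iid error assumption (autocorrelation + compositional
        # structure), so F tests on tracked cohorts over-reject under the
        # null.  Per-animal random effects are out of scope; this test keeps
        # the behavior visible.
        rej = 0
        reps = 60
        for rep in range(reps):
            a = simulate_cohort("naive_male", n_animals=4, seed=50_000 + 2 * rep,
                                duration_s=150)
            b = simulate_cohort("naive_male", n_animals=4, seed=50_001 + 2 * rep,
                                duration_s=150)

            def pts(cohort):
                profiles = [
                    occupancy_profile(t, cohort.arena, cohort.calibration)
                    for t in cohort.tracks
                ]
                return pooled_points(profiles)

            res = compare_preference(*pts(a), *pts(b), parameter="t_peak")
            rej += res.p_value < 0.05
        assert rej / reps > 0.10


class TestTTests:
    def test_welch_identical_samples(self):
        res = welch_t_test([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_welch_textbook_example(self):
        res = welch_t_test([1, 2, 3, 4], [3, 4, 5, 6])
        assert res.statistic == pytest.approx(-2.191, abs=1e-3)
        assert res.df == pytest.approx(6.0)
        assert res.p_value == pytest.approx(0.0707, abs=1e-3)

    def test_welch_zero_variance_both_rejected(self):
        with pytest.raises(UndefinedTestError):
            welch_t_test([0, 0, 0], [1, 1, 1])

    def test_welch_reduces_to_pooled_t_under_equal_variance(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.5, 1, 10)
        ours = welch_t_test(a, b)
        pooled = stats.ttest_ind(a, b, equal_var=True)
        # equal n: Welch statistic equals the pooled statistic exactly
        assert ours.statistic == pytest.approx(pooled.statistic, abs=1e-9)

    def test_paired_differences_example(self):
        res = paired_t_test([0, 0, 0], [1, 2, 3])
        assert res.statistic == pytest.approx(2 / (1 / np.sqrt(3)), abs=1e-6)
        assert res.df == 2
        assert res.p_value == pytest.approx(0.0742, abs=1e-3)

    def test_paired_sign_symmetry(self):
        up = paired_t_test([0, 0, 0, 0], [1, 3, 2, 5])
        down = paired_t_test([1, 3, 2, 5], [0, 0, 0, 0])
        assert up.statistic == pytest.approx(-down.statistic)
        assert up.p_value == pytest.approx(down.p_value)

    def test_paired_identical_rejected(self):
        with pytest.raises(UndefinedTestError):
            paired_t_test([1, 2, 3], [1, 2, 3])


class TestEffectSizeAndPower:
    def test_pooled_sigma_formula(self):
        es = cohens_d(1.5, 72.0, 50, 72.0, 50)
        assert es.pooled_sigma == pytest.approx(1.2)
        assert es.d == pytest.approx(1.25)

    def test_zero_effect(self):
        assert cohens_d(0.0, 72.0, 50, 72.0, 50).d == 0.0

    def test_sigma_scaling_law(self):
        base = cohens_d(1.5, 72.0, 50, 72.0, 50)
        doubled = cohens_d(1.5, 144.0, 50, 144.0, 50)
        assert doubled.pooled_sigma == pytest.approx(base.pooled_sigma * np.sqrt(2))
        assert doubled.d == pytest.approx(base.d / np.sqrt(2))

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            cohens_d(1.5, 0.0, 50, 0.0, 50)

    @pytest.mark.parametrize(
        "delta, sigma, expected",
        [(1.5, 1.2, 11), (2.0, 1.2, 6)],
    )
    def test_planning_reference_values(self, delta, sigma, expected):
        assert sample_size_per_group(delta / sigma) == expected

    def test_closed_form_small_effect(self):
        assert sample_size_per_group(0.625) == 41

    def test_monotonic_in_effect_and_power(self):
        ds = [0.3, 0.5, 0.8, 1.2, 2.0]
        ns = [sample_size_per_group(d) for d in ds]
        assert all(a >= b for a, b in zip(ns, ns[1:]))
        n80 = sample_size_per_group(1.0, PowerSpec(power=0.80))
        n90 = sample_size_per_group(1.0, PowerSpec(power=0.90))
        assert n90 >= n80

    def test_noncentral_t_at_least_normal_approx(self):
        for d in (0.5, 1.0, 1.25, 5.0 / 3.0):
            n_norm = sample_size_per_group(d)
            n_exact = sample_size_per_group(d, PowerSpec(method="noncentral_t"))
            assert n_exact >= n_norm

    def test_zero_effect_rejected(self):
        with pytest.raises(DegenerateDataError):
            sample_size_per_group(0.0)
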