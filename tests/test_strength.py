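"""f95 statistic, per-frame maxima, diameter measurement, group comparison."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pillarforce as pf
from pillarforce import strength
from pillarforce.strength import StrengthResult, compare_groups, f95, frame_max_forces


def percentile_oracle(values, level):
    """Brute-force order-statistic interpolation, coded independently."""
    xs = sorted(float(v) for v in values)
    rank = (len(xs) - 1) * level / 100.0
    below = math.floor(rank)
    above = math.ceil(rank)
    if below == above:
        return xs[below]
    return xs[below] * (above - rank) + xs[above] * (rank - below)


class TestFrameMaxForces:
    def test_single_contacted_pillar_passes_through(self):
        force = np.array([[1.0], [2.0], [0.5]])
        contact = np.ones((3, 1), dtype=bool)
        np.testing.assert_array_equal(
            frame_max_forces(force, contact), [1.0, 2.0, 0.5]
        )

    def test_maximum_over_contacted_pillars(self):
        force = np.array([[1.0, 2.5, 0.3]])
        contact = np.ones((1, 3), dtype=bool)
        assert frame_max_forces(force, contact)[0] == 2.5

    def test_frames_without_contact_are_omitted(self):
        force = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        contact = np.array([[True, True], [False, False], [True, False]])
        np.testing.assert_array_equal(frame_max_forces(force, contact), [2.0, 5.0])

    def test_missing_forces_never_contribute(self):
        force = np.array([[np.nan, 2.0], [np.nan, np.nan]])
        contact = np.ones((2, 2), dtype=bool)
        np.testing.assert_array_equal(frame_max_forces(force, contact), [2.0])

    def test_ledger_episode_maxima_recovered(self, arena, episode45, tracked45):
        _, ledger = episode45
        from pillarforce.beam import deflection_to_force

        forces = deflection_to_force(
            tracked45.deflection_magnitude_um, arena.beam_spec
        )
        measured = frame_max_forces(forces, tracked45.contact)
        truth = ledger.frame_max_forces()
        assert len(measured) == len(truth)
        np.testing.assert_allclose(measured, truth, atol=0.6)  # 0.5 px tracking


class TestF95:
    def test_constant_series(self):
        assert f95([3.2] * 100) == 3.2

    def test_one_to_hundred_matches_hand_interpolation(self):
        # frozen from the brute-force oracle before wiring it up: 95.05
        assert f95(np.arange(1.0, 101.0)) == pytest.approx(95.05, abs=1e-12)

    def test_matches_independent_oracle_on_random_series(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            xs = rng.gamma(2.0, 3.0, rng.integers(20, 400))
            assert f95(xs) == pytest.approx(percentile_oracle(xs, 95), rel=1e-12)
            assert f95(xs, level=50) == pytest.approx(
                percentile_oracle(xs, 50), rel=1e-12
            )
            # and against the reference library implementation
            assert f95(xs) == pytest.approx(np.percentile(xs, 95), rel=1e-12)

    def test_nearest_rank_method(self):
        xs = np.arange(1.0, 101.0)
        assert f95(xs, method="nearest") == 95.0
        assert f95([5.0] * 30, method="nearest") == 5.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        xs = rng.normal(10, 2, 200)
        assert f95(xs) == f95(rng.permutation(xs))

    @given(
        c=st.floats(0.1, 10), b=st.floats(-5, 5),
        seed=st.integers(0, 1000),
    )
    def test_affine_equivariance(self, c, b, seed):
        xs = np.random.default_rng(seed).normal(0, 1, 60)
        assert f95(c * xs + b) == pytest.approx(c * f95(xs) + b, rel=1e-9, abs=1e-9)

    def test_short_series_refused(self):
        with pytest.raises(ValueError, match="at least"):
            f95(np.ones(5))

    def test_result_bounded_by_series_range(self):
        xs = np.random.default_rng(9).uniform(0, 7, 101)
        assert xs.min() <= f95(xs) <= xs.max()


class TestMeasureDiameter:
    def test_constant_width_strip_is_exact(self):
        mask = np.zeros((60, 200), dtype=bool)
        mask[20:40, 10:190] = True  # 20 px wide strip
        d = strength.measure_diameter(mask, pixel_size_um_per_px=1.0)
        assert d == pytest.approx(20.0, abs=0.1)

    def test_doubling_pixel_size_doubles_diameter(self):
        mask = np.zeros((60, 200), dtype=bool)
        mask[20:40, 10:190] = True
        d1 = strength.measure_diameter(mask, 1.0)
        d2 = strength.measure_diameter(mask, 2.0)
        assert d2 == pytest.approx(2 * d1, rel=1e-12)

    def test_rendered_worm_tube_width_within_five_percent(self, arena, episode45):
        from pillarforce import tracking

        stack, ledger = episode45
        masks = tracking.segment_worm(stack)
        d = strength.measure_diameter(masks, arena.pixel_size_um_per_px)
        assert d == pytest.approx(ledger.worm_diameter_um, rel=0.05)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            strength.measure_diameter(np.zeros((10, 10), dtype=bool), 1.0)


class TestCompareGroups:
    def test_identical_cohorts_zero_difference(self):
        xs = [1.0, 2.0, 3.0, 4.0]
        res = compare_groups(xs, xs)
        assert res.mean_diff == 0.0
        assert res.percent_of_reference == 0.0

    def test_accepts_strength_results_and_drops_excluded(self):
        cohort = [
            StrengthResult("w1", f95_uN=2.0, frame_max_uN=np.array([1.0, 2.0]),
                           n_frames_used=2),
            StrengthResult("w2", f95_uN=3.0, frame_max_uN=np.array([1.0, 3.0]),
                           n_frames_used=2),
            StrengthResult("w3", qc_status="stationary"),
        ]
        res = compare_groups(cohort, [2.0, 3.0, 4.0])
        assert res.n_a == 2 and res.n_b == 3

    def test_zero_variance_pair_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            compare_groups([1.0, 1.0], [2.0, 3.0, 4.0])

    def test_clear_separation_detected(self):
        rng = np.random.default_rng(5)
        a = rng.normal(1.0, 0.1, 25)
        b = rng.normal(1.5, 0.1, 25)
        assert compare_groups(a, b).p_value < 1e-6


class TestStrengthResult:
    def test_excluded_episode_cannot_carry_f95(self):
        with pytest.raises(ValueError, match="no f95"):
            StrengthResult("w", f95_uN=1.0, qc_status="stationary")

    def test_f95_must_lie_in_series_range(self):
        with pytest.raises(ValueError, match="range"):
            StrengthResult("w", frame_max_uN=np.array([1.0, 2.0]), f95_uN=5.0,
                           n_frames_used=2)

    def test_cohort_summary_reproduces_design_skeleton(self):
        rng = np.random.default_rng(11)
        results = []
        for strain in ("WT", "mut"):
            for treatment in ("C", "M1", "M2", "P1", "P2"):
                for day in (1, 3, 5):
                    for i in range(3):
                        val = float(rng.uniform(1, 5))
                        results.append(
                            StrengthResult(
                                f"{strain}-{treatment}-{day}-{i}", strain=strain,
                                treatment=treatment, day=day,
                                frame_max_uN=np.array([val]), f95_uN=val,
                                n_frames_used=1,
                            )
                        )
        table = strength.cohort_summary(results)
        assert len(table) == 2 * 5 * 3
        assert set(table["day"]) == {1, 3, 5}
        assert (table["n"] == 3).all()
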