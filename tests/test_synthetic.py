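"""Generators: arenas, rendered episodes, thrash series, cohorts, OCR runs."""

import numpy as np
import pytest

import pillarforce as pf
from pillarforce.synthetic import (
    DEFAULT_OCR_PLAN,
    ForceProgram,
    WormKinematics,
    gen_ocr_run,
    gen_paralysis_cohort,
    gen_thrash_series,
    render_frame,
)
from pillarforce.tracking import detect_pillars


class TestArena:
    def test_square_lattice_zero_jitter_is_exact_grid(self):
        a = pf.gen_arena(n_rows=3, n_cols=3, lattice_spacing_um=100.0, jitter_frac=0.0)
        assert a.n_pillars == 9
        m = 50.0 + 40.0  # margin = spacing/2 + diameter
        expected = np.array(
            [[m + 100 * c, m + 100 * r] for r in range(3) for c in range(3)]
        )
        np.testing.assert_allclose(a.rest_centers_um, expected, atol=0)

    def test_deterministic_given_seed(self):
        a1 = pf.gen_arena(jitter_frac=0.03, seed=9)
        a2 = pf.gen_arena(jitter_frac=0.03, seed=9)
        np.testing.assert_array_equal(a1.rest_centers_um, a2.rest_centers_um)

    def test_triangular_lattice_matches_hand_built_coordinates(self):
        s = 100.0
        a = pf.gen_arena(
            n_rows=5, n_cols=2, lattice_spacing_um=s, lattice_kind="triangular",
            jitter_frac=0.0,
        )
        m = 0.5 * s + 40.0
        pitch = s * np.sqrt(3) / 2
        # hand-enumerated 5-row patch: odd rows offset by spacing/2
        expected = []
        for r in range(5):
            off = s / 2 if r % 2 == 1 else 0.0
            for c in range(2):
                expected.append([m + off + s * c, m + pitch * r])
        np.testing.assert_allclose(a.rest_centers_um, np.array(expected), atol=1e-9)

    def test_overlapping_pillars_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            pf.gen_arena(lattice_spacing_um=30.0, pillar_diameter_um=40.0)

    def test_jitter_bounded_to_five_percent(self):
        with pytest.raises(ValueError):
            pf.gen_arena(jitter_frac=0.2)


class TestRenderEpisode:
    def test_zero_force_program_leaves_all_pillars_at_rest(self, arena):
        spec = pf.EpisodeSpec(duration_s=2, noise_sigma=0.0,
                              illumination_gradient=0.0, seed=0)
        stack, ledger = pf.render_episode(
            arena, spec, forces=ForceProgram(f_max_uN=0.0)
        )
        assert np.all(ledger.deflection_um == 0)
        assert np.all(ledger.force_uN == 0)
        # pillars render at their rest centers in every frame
        for frame in stack[::5]:
            centers = detect_pillars(frame, arena.pillar_diameter_um)
            assert len(centers) == arena.n_pillars
            d = np.linalg.norm(
                np.sort(centers, axis=0) - np.sort(arena.rest_centers_um, axis=0),
                axis=1,
            )
            assert d.max() < 0.5

    def test_single_pillar_offset_matches_hand_computed_deflection(self):
        # compliance of the default pillar is 1.1009 um/uN (independent
        # arithmetic); a 3 uN force must shift the rendered center by
        # 3 * 1.1009... um = 3.3028 px at 1 um/px
        arena = pf.gen_arena(n_rows=1, n_cols=1)
        f_true = 3.0
        delta = arena.compliance_um_per_uN * f_true
        assert delta == pytest.approx(3.302783379043012, rel=1e-12)
        frame = render_frame(
            arena, None, 60.0, np.array([[delta, 0.0]])
        )
        (center,) = detect_pillars(frame, arena.pillar_diameter_um)
        offset = center[0] - arena.rest_centers_um[0, 0] / arena.pixel_size_um_per_px
        assert offset == pytest.approx(delta, abs=0.3)

    def test_noise_free_render_is_bit_identical_across_calls(self, arena,
                                                             clean_episode):
        stack1, _ = clean_episode
        spec = pf.EpisodeSpec(duration_s=6.0, frame_rate_hz=5.0, noise_sigma=0.0,
                              illumination_gradient=0.0, seed=2)
        stack2, _ = pf.render_episode(arena, spec)
        np.testing.assert_array_equal(stack1, stack2)

    def test_noisy_render_is_deterministic_given_seed(self, arena, episode45):
        stack1, _ = episode45
        stack2, _ = pf.render_episode(
            arena, pf.EpisodeSpec(duration_s=9.0, frame_rate_hz=5.0, seed=5)
        )
        np.testing.assert_array_equal(stack1, stack2)

    def test_ledger_internally_consistent(self, arena, episode45):
        _, ledger = episode45
        comp = arena.compliance_um_per_uN
        mags = np.linalg.norm(ledger.deflection_um, axis=-1)
        np.testing.assert_allclose(
            mags[ledger.contact], comp * ledger.force_uN[ledger.contact], rtol=1e-12
        )
        assert np.all(ledger.force_uN[~ledger.contact] == 0)
        assert np.all(mags[~ledger.contact] == 0)
        assert ledger.worm_diameter_um > 0

    def test_worm_wider_than_gap_is_infeasible(self, arena):
        with pytest.raises(ValueError, match="infeasible"):
            pf.render_episode(
                arena, pf.EpisodeSpec(duration_s=1),
                worm=WormKinematics(diameter_um=90.0),
            )

    def test_imposed_strength_increases_with_diameter_when_coupled(self, arena):
        f95s = []
        for d in (50.0, 60.0, 70.0):
            spec = pf.EpisodeSpec(duration_s=9.0, seed=17)
            _, ledger = pf.render_episode(
                arena, spec,
                worm=WormKinematics(diameter_um=d),
                forces=ForceProgram(diameter_coupling=True),
            )
            f95s.append(ledger.f95())
        assert f95s[0] < f95s[1] < f95s[2]


class TestThrashSeries:
    def test_zero_frequency_noise_free_is_constant(self):
        ts = gen_thrash_series(0.0, duration_s=5, noise_sigma=0.0)
        assert np.all(ts.angle_rad == 0)

    def test_cycle_count_matches_frequency(self):
        # 1.5 Hz over 10 s -> 15 full cycles -> 30 zero crossings
        ts = gen_thrash_series(1.5, duration_s=10, noise_sigma=0.0)
        signs = np.sign(ts.angle_rad[ts.angle_rad != 0])  # drop exact zeros
        segments = np.sum(signs[1:] != signs[:-1]) + 1  # alternating lobes
        assert segments // 2 == 15

    def test_same_seed_same_noise(self):
        a = gen_thrash_series(1.0, seed=4).angle_rad
        b = gen_thrash_series(1.0, seed=4).angle_rad
        np.testing.assert_array_equal(a, b)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            gen_thrash_series(1.0, duration_s=-1)


class TestParalysisCohort:
    def test_zero_hazard_never_paralyzed(self):
        c = gen_paralysis_cohort(20, 0.0)
        assert c.counts_at(np.array([10, 1000, 1e6])).tolist() == [0, 0, 0]

    def test_huge_hazard_saturates_at_first_scored_time(self):
        c = gen_paralysis_cohort(50, 10.0, seed=1)
        assert c.counts_at(np.array([10.0]))[0] == 50

    def test_empirical_cdf_matches_exponential(self):
        # closed form: P(T <= 10) = 1 - exp(-0.5) for hazard 0.05/min
        lam, n = 0.05, 10_000
        c = gen_paralysis_cohort(n, lam, seed=12)
        frac = c.fractions_at(np.array([10.0]))[0]
        p = 1 - np.exp(-lam * 10)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) <= 3 * se

    def test_counts_non_decreasing(self):
        c = gen_paralysis_cohort(100, 0.07, seed=3)
        counts = c.counts_at(np.arange(10, 200, 10.0))
        assert np.all(np.diff(counts) >= 0)
        assert counts.max() <= 100

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            gen_paralysis_cohort(0, 0.1)
        with pytest.raises(ValueError):
            gen_paralysis_cohort(10, -0.1)


class TestOCRRun:
    def test_noise_free_cycles_equal_phase_levels(self):
        run = gen_ocr_run(basal=20, maximal=30, nonmito=4, noise_sd=0.0, n_wells=1)
        well = run.wells[0]
        phases = np.array(well.phases)
        assert np.all(well.values[phases == "basal"] == 20)
        assert np.all(well.values[phases == "maximal"] == 30)
        assert np.all(well.values[phases == "nonmito"] == 4)

    def test_default_plan_emits_19_cycles(self):
        run = gen_ocr_run(n_wells=1)
        assert len(run.wells[0].values) == sum(DEFAULT_OCR_PLAN) == 19

    def test_equal_levels_give_zero_spare_before_noise(self):
        run = gen_ocr_run(basal=25, maximal=25, noise_sd=0.0, n_wells=2)
        for well in run.wells:
            phases = np.array(well.phases)
            spare = (well.values[phases == "maximal"].mean()
                     - well.values[phases == "basal"].mean())
            assert spare == 0

    def test_invalid_levels_rejected(self):
        with pytest.raises(ValueError):
            gen_ocr_run(basal=-1)
        with pytest.raises(ValueError):
            gen_ocr_run(basal=10, maximal=5)
        with pytest.raises(ValueError):
            gen_ocr_run(worms_per_well=0)
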