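"""Pillar detection, rest-lattice estimation, deflection tracking, QC."""

import numpy as np
import pytest

import pillarforce as pf
from pillarforce import tracking
from pillarforce.synthetic import WormKinematics, render_frame
from pillarforce.tracking import PillarTracks


class TestDetectPillars:
    def test_single_pillar_localized_within_half_pixel(self):
        arena = pf.gen_arena(n_rows=1, n_cols=1)
        frame = render_frame(arena, None, 60.0, np.array([[2.3, -1.7]]))
        truth = arena.rest_centers_um[0] + [2.3, -1.7]
        (center,) = tracking.detect_pillars(frame, arena.pillar_diameter_um)
        assert np.linalg.norm(center - truth) < 0.5

    def test_blank_image_yields_empty_list(self):
        assert len(tracking.detect_pillars(np.zeros((64, 64)), 10)) == 0

    def test_non_2d_input_rejected(self):
        with pytest.raises(ValueError, match="2-D"):
            tracking.detect_pillars(np.zeros((3, 64, 64)), 10)

    def test_unreasonable_diameter_rejected(self):
        with pytest.raises(ValueError):
            tracking.detect_pillars(np.zeros((64, 64)), 2)
        with pytest.raises(ValueError):
            tracking.detect_pillars(np.zeros((64, 64)), 60)

    def test_jittered_lattice_all_recovered_within_half_pixel(self):
        arena = pf.gen_arena(n_rows=3, n_cols=3, jitter_frac=0.04, seed=8)
        frame = render_frame(arena, None, 60.0, np.zeros((9, 2)))
        centers = tracking.detect_pillars(frame, arena.pillar_diameter_um)
        assert len(centers) == 9
        truth = arena.rest_centers_um[
            np.lexsort((np.round(arena.rest_centers_um[:, 0]),
                        np.round(arena.rest_centers_um[:, 1])))
        ]
        assert np.linalg.norm(centers - truth, axis=1).max() < 0.5


class TestReferenceLattice:
    def test_config_centers_used_verbatim(self, arena):
        rest = tracking.build_reference_lattice(arena=arena)
        np.testing.assert_array_equal(rest, arena.rest_centers_um)

    def test_estimated_from_episode_within_half_pixel(self, arena, episode45):
        stack, _ = episode45
        rest = tracking.build_reference_lattice(
            stack=stack,
            expected_diameter_px=arena.pillar_diameter_um,
            pixel_size_um_per_px=arena.pixel_size_um_per_px,
            spacing_um=arena.lattice_spacing_um,
        )
        assert len(rest) == arena.n_pillars
        order = np.lexsort((np.round(rest[:, 0]), np.round(rest[:, 1])))
        truth = arena.rest_centers_um[
            np.lexsort((np.round(arena.rest_centers_um[:, 0]),
                        np.round(arena.rest_centers_um[:, 1])))
        ]
        assert np.linalg.norm(rest[order] - truth, axis=1).max() < 0.5


class TestTrackDeflections:
    def test_noise_free_recovery_within_half_pixel(self, arena, clean_episode):
        stack, ledger = clean_episode
        tracks = tracking.track_deflections(
            stack, arena.rest_centers_um, arena.pixel_size_um_per_px,
            pillar_diameter_um=arena.pillar_diameter_um,
            spacing_um=arena.lattice_spacing_um,
        )
        err = np.linalg.norm(tracks.displacement_um - ledger.deflection_um, axis=-1)
        assert np.nanmax(err) <= 0.5 * arena.pixel_size_um_per_px

    def test_identical_frames_give_identical_tracks(self, arena, episode45):
        stack, _ = episode45
        rep = np.repeat(stack[10][None], 4, axis=0)
        tracks = tracking.track_deflections(
            rep, arena.rest_centers_um, 1.0,
            pillar_diameter_um=arena.pillar_diameter_um,
            spacing_um=arena.lattice_spacing_um,
        )
        for t in range(1, 4):
            np.testing.assert_array_equal(
                tracks.displacement_um[t], tracks.displacement_um[0]
            )

    def test_static_stack_with_self_reference_has_zero_displacement(self, arena):
        frame = render_frame(arena, None, 60.0, np.zeros((arena.n_pillars, 2)))
        stack = np.repeat(
            (frame * 65535).astype(np.uint16)[None], 3, axis=0
        )
        detected = tracking.detect_pillars(stack[0], arena.pillar_diameter_um)
        tracks = tracking.track_deflections(
            stack, detected * arena.pixel_size_um_per_px, arena.pixel_size_um_per_px,
            pillar_diameter_um=arena.pillar_diameter_um,
            spacing_um=arena.lattice_spacing_um,
        )
        assert np.nanmax(np.abs(tracks.displacement_um)) < 0.05

    def test_doubling_pixel_size_doubles_micron_displacements(self, arena,
                                                              episode45):
        stack, _ = episode45
        kw = dict(pillar_diameter_um=arena.pillar_diameter_um,
                  spacing_um=arena.lattice_spacing_um)
        t1 = tracking.track_deflections(stack, arena.rest_centers_um, 1.0, **kw)
        t2 = tracking.track_deflections(
            stack, 2.0 * arena.rest_centers_um, 2.0,
            pillar_diameter_um=2 * arena.pillar_diameter_um,
            spacing_um=2 * arena.lattice_spacing_um,
        )
        np.testing.assert_allclose(
            t2.displacement_um, 2.0 * t1.displacement_um, rtol=0, atol=1e-9
        )

    def test_pillar_relabeling_leaves_displacements_unchanged(self, tracked45):
        order = np.arange(tracked45.n_pillars)[::-1]
        perm = tracked45.permuted(order)
        np.testing.assert_array_equal(
            perm.displacement_um, tracked45.displacement_um[:, order]
        )
        np.testing.assert_array_equal(perm.contact, tracked45.contact[:, order])

    def test_median_error_stays_below_one_pixel_at_double_noise(self, arena):
        spec = pf.EpisodeSpec(duration_s=6.0, noise_sigma=0.04, seed=21)
        stack, ledger = pf.render_episode(arena, spec)
        tracks = tracking.track_deflections(
            stack, arena.rest_centers_um, 1.0,
            pillar_diameter_um=arena.pillar_diameter_um,
            spacing_um=arena.lattice_spacing_um,
        )
        err = np.linalg.norm(tracks.displacement_um - ledger.deflection_um, axis=-1)
        assert np.nanmedian(err) <= 1.0 * arena.pixel_size_um_per_px


class TestClassifyContact:
    def test_ledger_agreement_at_default_noise(self, arena, episode45, tracked45):
        _, ledger = episode45
        agreement = (tracked45.contact == ledger.contact).mean()
        assert agreement >= 0.99

    def test_zero_displacements_give_no_contacts(self):
        tracks = PillarTracks(
            rest_centers_um=np.array([[10.0, 10.0], [50.0, 10.0]]),
            displacement_um=np.zeros((5, 2, 2)),
            confidence=np.ones((5, 2)),
            pixel_size_um_per_px=1.0,
        )
        out = tracking.classify_contact(tracks)
        assert not out.contact.any()

    def test_zero_threshold_flags_any_displacement(self):
        disp = np.zeros((4, 3, 2))
        disp[1, 2, 0] = 0.4
        tracks = PillarTracks(
            rest_centers_um=np.array([[10.0, 10.0], [50.0, 10.0], [90.0, 10.0]]),
            displacement_um=disp,
            confidence=np.ones((4, 3)),
            pixel_size_um_per_px=1.0,
        )
        out = tracking.classify_contact(tracks, k=0.0, sigma_noise_um=0.01)
        assert out.contact[1, 2]
        assert out.contact.sum() == 1

    def test_no_quiet_pillar_requires_explicit_threshold(self):
        disp = np.full((4, 2, 2), 5.0)
        tracks = PillarTracks(
            rest_centers_um=np.array([[10.0, 10.0], [50.0, 10.0]]),
            displacement_um=disp,
            confidence=np.ones((4, 2)),
            pixel_size_um_per_px=1.0,
        )
        with pytest.raises(ValueError, match="sigma_noise_um"):
            tracking.classify_contact(tracks)


class TestEpisodeQC:
    def test_moving_worm_passes(self, arena, episode45):
        stack, _ = episode45
        qc = tracking.qc_episode(stack, arena.pixel_size_um_per_px)
        assert qc.processed and qc.failure_reason is None
        assert qc.usable_for_strength
        assert qc.motion_score_um > 1.5

    def test_stationary_worm_flagged(self, arena):
        spec = pf.EpisodeSpec(duration_s=4.0, seed=6)
        worm = WormKinematics(speed_um_per_s=0.0, undulation_hz=0.0)
        stack, _ = pf.render_episode(arena, spec, worm=worm)
        qc = tracking.qc_episode(stack, arena.pixel_size_um_per_px)
        assert qc.processed
        assert qc.failure_reason == "stationary"
        assert not qc.usable_for_strength

    def test_unreadable_file_yields_processing_failure(self, tmp_path):
        bad = tmp_path / "truncated.tiff"
        bad.write_bytes(b"II*\x00garbage")
        qc = tracking.qc_episode(bad, 1.0)
        assert not qc.processed
        assert qc.failure_reason == "processing-failure"

    def test_qc_record_consistency_enforced(self):
        with pytest.raises(ValueError):
            tracking.EpisodeQC(processed=False, failure_reason=None,
                               motion_score_um=None)
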