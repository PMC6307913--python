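import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pillarforce as pf

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def arena():
    """Default 4x4 square arena (d=40, spacing=120, E=250 kPa, 1 um/px)."""
    return pf.gen_arena()


@pytest.fixture(scope="session")
def episode45(arena):
    """A 45-frame rendered episode with default noise, plus its ledger."""
    spec = pf.EpisodeSpec(duration_s=9.0, frame_rate_hz=5.0, seed=5)
    return pf.render_episode(arena, spec)


@pytest.fixture(scope="session")
def clean_episode(arena):
    """Noise- and shading-free 30-frame episode (bit-exact expectations)."""
    spec = pf.EpisodeSpec(
        duration_s=6.0, frame_rate_hz=5.0, noise_sigma=0.0,
        illumination_gradient=0.0, seed=2,
    )
    return pf.render_episode(arena, spec)


@pytest.fixture(scope="session")
def tracked45(arena, episode45):
    stack, _ = episode45
    from pillarforce import tracking

    rest = tracking.build_reference_lattice(arena=arena)
    tracks = tracking.track_deflections(
        stack, rest, arena.pixel_size_um_per_px,
        pillar_diameter_um=arena.pillar_diameter_um,
        spacing_um=arena.lattice_spacing_um,
    )
    masks = tracking.segment_worm(stack)
    return tracking.classify_contact(
        tracks, worm_masks=masks, pillar_diameter_um=arena.pillar_diameter_um
    )
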