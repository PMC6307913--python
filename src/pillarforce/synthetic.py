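"""Synthetic inputs with known ground truth for every pipeline stage.

No public image or assay data exist for the micropillar strength workflow, so
this module generates all of it:

* rendered pillar-arena time-lapse episodes in which a crawling worm deflects
  pillars by known, imposed forces (the :class:`GroundTruthLedger` records the
  truth frame by frame);
* sinusoidal head-bend angle series for the thrashing (swim) assay;
* exponential-hazard paralysis cohorts scored on a 10-minute grid for the
  levamisole assay;
* three-phase oxygen-consumption-rate (OCR) traces (basal / post-uncoupler
  maximal / post-azide non-mitochondrial) for plate respirometry.

Every generator is a pure function of its parameters and an integer seed; a
single seed fans out to independent per-component streams via
``numpy.random.SeedSequence.spawn``.

The renderer draws the worm as a constant-width tube around a serpenoid
midline and the pillars as dark anti-aliased disks.  A pillar is "in contact"
when its rest center lies within one worm radius plus one pillar radius of the
midline; contacted pillars are drawn displaced along the outward normal from
the nearest midline point by ``delta = C * F`` where ``C`` is the Timoshenko
compliance of the arena's pillars.  There is no pillar-pillar coupling, no
hydrodynamics, and no feedback of pillar stiffness on the worm's path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image, ImageDraw

from .beam import BeamSpec, compliance

__all__ = [
    "PillarArena",
    "EpisodeSpec",
    "WormKinematics",
    "ForceProgram",
    "GroundTruthLedger",
    "ThrashSeries",
    "ParalysisCohort",
    "OCRWell",
    "OCRRun",
    "gen_arena",
    "render_episode",
    "render_frame",
    "gen_thrash_series",
    "gen_paralysis_cohort",
    "gen_ocr_run",
    "DEFAULT_OCR_PLAN",
]

# Rendered intensity levels as fractions of the dynamic range.  Bright-field
# imaging of PDMS arenas: bright background, mid-gray worm body, dark pillars.
BACKGROUND_LEVEL = 0.82
WORM_LEVEL = 0.55
PILLAR_LEVEL = 0.22
EDGE_WIDTH_PX = 2.0  # anti-aliasing ramp width of the pillar edge


# ---------------------------------------------------------------------------
# Arena


@dataclass(frozen=True)
class PillarArena:
    """Geometry, material and calibration of the deformable pillar lattice."""

    pillar_diameter_um: float
    pillar_height_um: float
    contact_height_um: float
    lattice_spacing_um: float
    youngs_modulus_kPa: float
    poisson_ratio: float
    pixel_size_um_per_px: float
    image_shape_px: tuple[int, int]
    rest_centers_um: np.ndarray  # (n_pillars, 2) as (x, y) in um
    lattice_kind: str = "square"

    def __post_init__(self) -> None:
        d = self.pillar_diameter_um
        if d <= 0:
            raise ValueError("pillar diameter must be positive")
        if not (0 < self.contact_height_um <= self.pillar_height_um):
            raise ValueError("contact height must satisfy 0 < a <= L")
        if self.lattice_spacing_um <= d:
            raise ValueError(
                f"lattice spacing {self.lattice_spacing_um} um must exceed the "
                f"pillar diameter {d} um (pillars overlap at rest)"
            )
        if self.youngs_modulus_kPa <= 0:
            raise ValueError("Young's modulus must be positive")
        if not (0 <= self.poisson_ratio < 0.5):
            raise ValueError("Poisson ratio must lie in [0, 0.5)")
        if self.lattice_kind not in ("square", "triangular"):
            raise ValueError(f"unknown lattice kind {self.lattice_kind!r}")
        centers = np.asarray(self.rest_centers_um, dtype=float)
        object.__setattr__(self, "rest_centers_um", centers)
        h, w = self.image_shape_px
        extent = np.array([w, h], dtype=float) * self.pixel_size_um_per_px
        if np.any(centers < 0) or np.any(centers >= extent):
            raise ValueError("all rest centers must lie inside the image bounds")

    @property
    def n_pillars(self) -> int:
        return len(self.rest_centers_um)

    @property
    def beam_spec(self) -> BeamSpec:
        return BeamSpec(
            diameter_um=self.pillar_diameter_um,
            contact_height_um=self.contact_height_um,
            height_um=self.pillar_height_um,
            youngs_modulus_kPa=self.youngs_modulus_kPa,
            poisson_ratio=self.poisson_ratio,
        )

    @property
    def compliance_um_per_uN(self) -> float:
        return compliance(self.beam_spec)


def gen_arena(
    n_rows: int = 4,
    n_cols: int = 4,
    lattice_spacing_um: float = 120.0,
    lattice_kind: str = "square",
    pillar_diameter_um: float = 40.0,
    pillar_height_um: float = 87.0,
    contact_height_um: float = 40.0,
    youngs_modulus_kPa: float = 250.0,
    poisson_ratio: float = 0.49,
    pixel_size_um_per_px: float = 1.0,
    jitter_frac: float = 0.0,
    margin_um: float | None = None,
    seed: int = 0,
) -> PillarArena:
    """Build a pillar arena with rest centers on a regular lattice.

    ``jitter_frac`` adds seeded uniform jitter of at most that fraction of the
    lattice spacing (capped at 5%) to each rest center, emulating fabrication
    tolerance.  Deterministic given the seed.
    """
    if lattice_spacing_um <= pillar_diameter_um:
        raise ValueError("lattice spacing must exceed pillar diameter")
    if not (0 <= jitter_frac <= 0.05):
        raise ValueError("jitter_frac must lie in [0, 0.05]")
    s = lattice_spacing_um
    if margin_um is None:
        margin_um = 0.5 * s + pillar_diameter_um
    if lattice_kind == "square":
        xs = margin_um + s * np.arange(n_cols)
        ys = margin_um + s * np.arange(n_rows)
        gx, gy = np.meshgrid(xs, ys)
        centers = np.column_stack([gx.ravel(), gy.ravel()])
    elif lattice_kind == "triangular":
        row_pitch = s * np.sqrt(3.0) / 2.0
        rows = []
        for r in range(n_rows):
            offset = 0.5 * s if r % 2 == 1 else 0.0
            xs = margin_um + offset + s * np.arange(n_cols)
            ys = np.full(n_cols, margin_um + row_pitch * r)
            rows.append(np.column_stack([xs, ys]))
        centers = np.vstack(rows)
    else:
        raise ValueError(f"unknown lattice kind {lattice_kind!r}")

    if jitter_frac > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
        centers = centers + rng.uniform(-jitter_frac * s, jitter_frac * s, centers.shape)

    extent = centers.max(axis=0) + margin_um
    w = int(np.ceil(extent[0] / pixel_size_um_per_px))
    h = int(np.ceil(extent[1] / pixel_size_um_per_px))
    return PillarArena(
        pillar_diameter_um=pillar_diameter_um,
        pillar_height_um=pillar_height_um,
        contact_height_um=contact_height_um,
        lattice_spacing_um=lattice_spacing_um,
        youngs_modulus_kPa=youngs_modulus_kPa,
        poisson_ratio=poisson_ratio,
        pixel_size_um_per_px=pixel_size_um_per_px,
        image_shape_px=(h, w),
        rest_centers_um=centers,
        lattice_kind=lattice_kind,
    )


# ---------------------------------------------------------------------------
# Episodes


@dataclass(frozen=True)
class EpisodeSpec:
    """Acquisition parameters of one imaging episode (45 s at 5 frames/s)."""

    duration_s: float = 45.0
    frame_rate_hz: float = 5.0
    noise_sigma: float = 0.02
    illumination_gradient: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame rate must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))


@dataclass(frozen=True)
class WormKinematics:
    """Serpenoid crawling kinematics of the rendered worm.

    The midline is a traveling lateral wave on a straight body axis along +x:
    ``y(s, t) = y0 + A sin(2 pi s / wavelength + 2 pi f t + phase)`` with the
    head advancing at constant speed.  ``speed_um_per_s = 0`` together with
    ``undulation_hz = 0`` yields a stationary worm (QC test case).
    """

    length_um: float = 500.0
    diameter_um: float = 60.0
    amplitude_um: float = 40.0
    wavelength_um: float = 250.0
    undulation_hz: float = 0.5
    speed_um_per_s: float = 7.5
    start_head_x_um: float = 150.0
    center_y_um: float | None = None  # None -> image center
    phase_rad: float = 0.0
    n_midline_points: int = 161

    def __post_init__(self) -> None:
        if self.length_um <= 0 or self.diameter_um <= 0:
            raise ValueError("worm length and diameter must be positive")

    def midline(self, t_s: float, arena: PillarArena) -> np.ndarray:
        """Midline polyline (n, 2) in um at time ``t_s``, head first."""
        h, w = arena.image_shape_px
        y0 = self.center_y_um
        if y0 is None:
            y0 = 0.5 * h * arena.pixel_size_um_per_px
        s = np.linspace(0.0, self.length_um, self.n_midline_points)
        x = self.start_head_x_um + self.speed_um_per_s * t_s - s
        y = y0 + self.amplitude_um * np.sin(
            2.0 * np.pi * s / self.wavelength_um
            + 2.0 * np.pi * self.undulation_hz * t_s
            + self.phase_rad
        )
        return np.column_stack([x, y])


@dataclass(frozen=True)
class ForceProgram:
    """How imposed forces are assigned to contacted pillars.

    Each (frame, pillar) contact receives ``F = f_scale * U`` with
    ``U ~ Uniform(f_min_frac, 1)`` drawn from the episode's force stream.
    With ``diameter_coupling`` enabled the scale grows as ``(D / D_ref)^3``,
    so that imposed strength increases strictly with body diameter across a
    simulated cohort.
    """

    f_max_uN: float = 12.0
    f_min_frac: float = 0.2
    diameter_coupling: bool = False
    reference_diameter_um: float = 60.0

    def scale_for(self, worm_diameter_um: float) -> float:
        if not self.diameter_coupling:
            return self.f_max_uN
        return self.f_max_uN * (worm_diameter_um / self.reference_diameter_um) ** 3


@dataclass
class GroundTruthLedger:
    """Imposed forces, deflections and contact truth for one episode."""

    worm_diameter_um: float
    pixel_size_um_per_px: float
    frame_rate_hz: float
    midlines_um: list[np.ndarray]  # per frame, (n, 2)
    force_uN: np.ndarray  # (T, P) imposed force magnitude, 0 off contact
    deflection_um: np.ndarray  # (T, P, 2) imposed deflection vector
    contact: np.ndarray  # (T, P) bool
    rest_centers_um: np.ndarray  # (P, 2)

    @property
    def n_frames(self) -> int:
        return self.force_uN.shape[0]

    @property
    def n_pillars(self) -> int:
        return self.force_uN.shape[1]

    def frame_max_forces(self) -> np.ndarray:
        """Per-frame maximum imposed force over contacted pillars.

        Frames with no contacted pillar are omitted (matching the measurement
        convention of scoring only frames with pillar contact).
        """
        has_contact = self.contact.any(axis=1)
        masked = np.where(self.contact, self.force_uN, -np.inf)
        return masked[has_contact].max(axis=1)

    def f95(self, level: float = 95.0) -> float:
        from .strength import f95 as _f95

        return _f95(self.frame_max_forces(), level=level)

    def to_dataframe(self):
        """Long-form (frame, pillar) table mirroring the ledger CSV layout."""
        import pandas as pd

        t_idx, p_idx = np.meshgrid(
            np.arange(self.n_frames), np.arange(self.n_pillars), indexing="ij"
        )
        return pd.DataFrame(
            {
                "frame": t_idx.ravel(),
                "pillar_id": p_idx.ravel(),
                "x_um": np.tile(self.rest_centers_um[:, 0], self.n_frames),
                "y_um": np.tile(self.rest_centers_um[:, 1], self.n_frames),
                "dx_um": self.deflection_um[..., 0].ravel(),
                "dy_um": self.deflection_um[..., 1].ravel(),
                "force_uN": self.force_uN.ravel(),
                "contact": self.contact.ravel().astype(int),
            }
        )


def _point_segment_distances(points: np.ndarray, polyline: np.ndarray):
    """Distance from each point to a polyline, plus the nearest polyline point.

    points: (P, 2); polyline: (M, 2).  Returns (dist (P,), nearest (P, 2)).
    """
    a = polyline[:-1]  # (S, 2)
    b = polyline[1:]
    ab = b - a
    denom = np.einsum("sd,sd->s", ab, ab)
    denom = np.where(denom == 0, 1.0, denom)
    ap = points[:, None, :] - a[None, :, :]  # (P, S, 2)
    t = np.clip(np.einsum("psd,sd->ps", ap, ab) / denom, 0.0, 1.0)
    proj = a[None, :, :] + t[..., None] * ab[None, :, :]
    d2 = np.sum((points[:, None, :] - proj) ** 2, axis=-1)
    idx = np.argmin(d2, axis=1)
    rows = np.arange(len(points))
    return np.sqrt(d2[rows, idx]), proj[rows, idx]


def _worm_polygon(midline: np.ndarray, diameter_um: float) -> np.ndarray:
    """Closed polygon outline of a constant-width tube around the midline."""
    r = 0.5 * diameter_um
    tangent = np.gradient(midline, axis=0)
    norm = np.linalg.norm(tangent, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    tangent = tangent / norm
    normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])
    left = midline + r * normal
    right = midline - r * normal
    # Semicircular end caps at head (index 0) and tail (last index).
    thetas = np.linspace(0, np.pi, 9)[1:-1]

    def cap(point, t_dir, n_dir):
        # sweep from +normal through -tangent... direction outward along -t
        return np.array(
            [point + r * (np.cos(th) * n_dir - np.sin(th) * t_dir) for th in thetas]
        )

    head_cap = cap(midline[0], -tangent[0], normal[0])
    tail_cap = cap(midline[-1], tangent[-1], -normal[-1])
    return np.vstack([left, tail_cap, right[::-1], head_cap[::-1]])


def _draw_pillar(img: np.ndarray, illum: np.ndarray, cx_px: float, cy_px: float,
                 radius_px: float) -> None:
    """Blend an anti-aliased dark disk into ``img`` at sub-pixel position."""
    h, w = img.shape
    half = int(np.ceil(radius_px + EDGE_WIDTH_PX)) + 1
    x0 = max(int(np.floor(cx_px)) - half, 0)
    x1 = min(int(np.floor(cx_px)) + half + 1, w)
    y0 = max(int(np.floor(cy_px)) - half, 0)
    y1 = min(int(np.floor(cy_px)) + half + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - cx_px, yy - cy_px)
    cov = np.clip((radius_px + 0.5 * EDGE_WIDTH_PX - dist) / EDGE_WIDTH_PX, 0.0, 1.0)
    patch = img[y0:y1, x0:x1]
    img[y0:y1, x0:x1] = patch * (1 - cov) + PILLAR_LEVEL * illum[y0:y1, x0:x1] * cov


def _illumination_field(shape: tuple[int, int], gradient: float) -> np.ndarray:
    h, w = shape
    ramp = np.linspace(-0.5, 0.5, w, dtype=float)
    return np.tile(1.0 + gradient * ramp, (h, 1))


def render_frame(
    arena: PillarArena,
    midline_um: np.ndarray | None,
    worm_diameter_um: float,
    deflections_um: np.ndarray,
    illum: np.ndarray | None = None,
) -> np.ndarray:
    """Render one noiseless frame as float in [0, 1]."""
    h, w = arena.image_shape_px
    if illum is None:
        illum = _illumination_field((h, w), 0.0)
    img = BACKGROUND_LEVEL * illum.copy()
    px = arena.pixel_size_um_per_px
    if midline_um is not None:
        poly = _worm_polygon(midline_um, worm_diameter_um) / px
        pil = Image.new("1", (w, h), 0)
        ImageDraw.Draw(pil).polygon([(float(x), float(y)) for x, y in poly], fill=1)
        inside = np.asarray(pil, dtype=bool)
        img[inside] = WORM_LEVEL * illum[inside]
    radius_px = 0.5 * arena.pillar_diameter_um / px
    for p in range(arena.n_pillars):
        cx, cy = (arena.rest_centers_um[p] + deflections_um[p]) / px
        _draw_pillar(img, illum, cx, cy, radius_px)
    return img


def render_episode(
    arena: PillarArena,
    episode: EpisodeSpec | None = None,
    worm: WormKinematics | None = None,
    forces: ForceProgram | None = None,
) -> tuple[np.ndarray, GroundTruthLedger]:
    """Render a full episode and its ground-truth ledger.

    Returns ``(stack, ledger)`` with ``stack`` a ``(T, H, W)`` uint16 array.
    Deterministic given ``episode.seed``.
    """
    episode = episode or EpisodeSpec()
    worm = worm or WormKinematics()
    forces = forces or ForceProgram()

    gap = arena.lattice_spacing_um - arena.pillar_diameter_um
    if worm.diameter_um >= gap:
        raise ValueError(
            f"worm diameter {worm.diameter_um} um does not fit the lattice gap "
            f"{gap} um; rendering infeasible"
        )

    ss = np.random.SeedSequence([int(episode.seed), 202])
    force_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    n_frames = episode.n_frames
    n_pillars = arena.n_pillars
    comp = arena.compliance_um_per_uN
    contact_radius = 0.5 * worm.diameter_um + 0.5 * arena.pillar_diameter_um
    f_scale = forces.scale_for(worm.diameter_um)

    h, w = arena.image_shape_px
    illum = _illumination_field((h, w), episode.illumination_gradient)

    stack = np.empty((n_frames, h, w), dtype=np.uint16)
    midlines: list[np.ndarray] = []
    force_tab = np.zeros((n_frames, n_pillars))
    defl_tab = np.zeros((n_frames, n_pillars, 2))
    contact_tab = np.zeros((n_frames, n_pillars), dtype=bool)

    for t in range(n_frames):
        time_s = t / episode.frame_rate_hz
        mid = worm.midline(time_s, arena)
        midlines.append(mid)
        dist, nearest = _point_segment_distances(arena.rest_centers_um, mid)
        in_contact = dist <= contact_radius
        contact_tab[t] = in_contact
        if in_contact.any():
            idx = np.flatnonzero(in_contact)
            mags = f_scale * force_rng.uniform(forces.f_min_frac, 1.0, idx.size)
            outward = arena.rest_centers_um[idx] - nearest[idx]
            nrm = np.linalg.norm(outward, axis=1, keepdims=True)
            nrm[nrm == 0] = 1.0
            outward = outward / nrm
            force_tab[t, idx] = mags
            defl_tab[t, idx] = comp * mags[:, None] * outward

        frame = render_frame(arena, mid, worm.diameter_um, defl_tab[t], illum)
        if episode.noise_sigma > 0:
            frame = frame + noise_rng.normal(0.0, episode.noise_sigma, frame.shape)
        np.clip(frame, 0.0, 1.0, out=frame)
        stack[t] = np.round(frame * 65535.0).astype(np.uint16)

    ledger = GroundTruthLedger(
        worm_diameter_um=worm.diameter_um,
        pixel_size_um_per_px=arena.pixel_size_um_per_px,
        frame_rate_hz=episode.frame_rate_hz,
        midlines_um=midlines,
        force_uN=force_tab,
        deflection_um=defl_tab,
        contact=contact_tab,
        rest_centers_um=arena.rest_centers_um.copy(),
    )
    return stack, ledger


# ---------------------------------------------------------------------------
# Thrashing


@dataclass(frozen=True)
class ThrashSeries:
    """Head-bend angle series for one 10-s (or longer) swim window."""

    time_s: np.ndarray
    angle_rad: np.ndarray
    true_frequency_hz: float
    seed: int

    @property
    def sample_rate_hz(self) -> float:
        if len(self.time_s) < 2:
            return 0.0
        return 1.0 / float(self.time_s[1] - self.time_s[0])


def gen_thrash_series(
    true_frequency_hz: float,
    duration_s: float = 10.0,
    amplitude_rad: float = 1.0,
    noise_sigma: float = 0.1,
    sample_rate_hz: float = 30.0,
    seed: int = 0,
) -> ThrashSeries:
    """Sinusoidal bend-angle series: ``A sin(2 pi f t)`` plus Gaussian noise."""
    if true_frequency_hz < 0:
        raise ValueError("frequency must be non-negative")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    angle = amplitude_rad * np.sin(2.0 * np.pi * true_frequency_hz * t)
    if noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 303]))
        angle = angle + rng.normal(0.0, noise_sigma, n)
    return ThrashSeries(time_s=t, angle_rad=angle, true_frequency_hz=true_frequency_hz,
                        seed=seed)


# ---------------------------------------------------------------------------
# Levamisole paralysis


@dataclass(frozen=True)
class ParalysisCohort:
    """One strain/condition cohort with latent exponential paralysis times."""

    n_worms: int
    hazard_per_min: float
    latent_times_min: np.ndarray
    score_interval_min: float = 10.0
    label: str = ""

    def counts_at(self, times_min: np.ndarray) -> np.ndarray:
        """Number paralyzed at each scored time (non-decreasing, <= n)."""
        t = np.asarray(times_min, dtype=float)
        return (self.latent_times_min[None, :] <= t[:, None]).sum(axis=1)

    def fractions_at(self, times_min: np.ndarray) -> np.ndarray:
        return self.counts_at(times_min) / self.n_worms

    def all_paralyzed_by(self, t_min: float) -> bool:
        return bool(np.all(self.latent_times_min <= t_min))


def gen_paralysis_cohort(
    n: int,
    hazard_per_min: float,
    seed: int = 0,
    score_interval_min: float = 10.0,
    label: str = "",
) -> ParalysisCohort:
    """Cohort of ``n`` worms with i.i.d. exponential(hazard) paralysis times."""
    if n <= 0:
        raise ValueError("cohort size must be positive")
    if hazard_per_min < 0:
        raise ValueError("hazard must be non-negative")
    if hazard_per_min == 0:
        times = np.full(n, np.inf)
    else:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 404]))
        times = rng.exponential(1.0 / hazard_per_min, n)
    return ParalysisCohort(
        n_worms=n,
        hazard_per_min=hazard_per_min,
        latent_times_min=times,
        score_interval_min=score_interval_min,
        label=label,
    )


# ---------------------------------------------------------------------------
# Oxygen consumption


DEFAULT_OCR_PLAN = (5, 9, 5)  # basal / post-FCCP maximal / post-azide cycles
OCR_PHASES = ("basal", "maximal", "nonmito")


@dataclass(frozen=True)
class OCRWell:
    """Per-cycle OCR trace for one plate well."""

    label: str
    worms_per_well: int
    values: np.ndarray  # raw OCR per cycle, well units
    phases: tuple[str, ...]  # phase label per cycle, in order

    def __post_init__(self) -> None:
        if self.worms_per_well <= 0:
            raise ValueError("worms per well must be positive")
        if len(self.values) != len(self.phases):
            raise ValueError("one phase label per cycle required")


@dataclass(frozen=True)
class OCRRun:
    """A set of wells measured under a common phase plan."""

    wells: tuple[OCRWell, ...]
    plan: tuple[int, int, int] = DEFAULT_OCR_PLAN


def gen_ocr_run(
    basal: float = 20.0,
    maximal: float = 30.0,
    nonmito: float = 4.0,
    worms_per_well: int = 20,
    n_wells: int = 5,
    noise_sd: float = 2.0,
    label: str = "WT",
    plan: tuple[int, int, int] = DEFAULT_OCR_PLAN,
    seed: int = 0,
) -> OCRRun:
    """Three-phase OCR traces: phase level plus additive Gaussian noise.

    Default levels follow the plate design of 20 worms per well with five
    wells per condition; phase plan is 5 basal cycles, 9 after the uncoupler,
    5 after azide.
    """
    if min(basal, maximal, nonmito) < 0:
        raise ValueError("OCR levels must be non-negative")
    if not (maximal >= basal >= nonmito):
        raise ValueError("levels must satisfy maximal >= basal >= nonmito")
    if worms_per_well <= 0:
        raise ValueError("worms per well must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 505]))
    levels = np.concatenate(
        [np.full(plan[0], basal), np.full(plan[1], maximal), np.full(plan[2], nonmito)]
    )
    phases = tuple(
        [OCR_PHASES[0]] * plan[0] + [OCR_PHASES[1]] * plan[1] + [OCR_PHASES[2]] * plan[2]
    )
    wells = []
    for _ in range(n_wells):
        values = levels + rng.normal(0.0, noise_sd, levels.size) if noise_sd > 0 \
            else levels.copy()
        wells.append(
            OCRWell(label=label, worms_per_well=worms_per_well, values=values,
                    phases=phases)
        )
    return OCRRun(wells=tuple(wells), plan=plan)
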