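"""Per-pillar, per-frame deflection tracking from grayscale image stacks.

Pillars are dark, homogeneous circles; they are localized by normalized
cross-correlation against a rendered disk template with quadratic sub-pixel
peak refinement.  Rest positions come either from an arena config (used
verbatim) or are estimated from the stack as per-pillar medians over frames
where the pillar is not contacted (one re-estimation pass after provisional
contact flagging).  Displacements are reported in micrometres; a pillar that
cannot be localized in a frame is marked missing (NaN) with zero confidence
rather than interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.feature import match_template, peak_local_max

__all__ = [
    "PillarTracks",
    "EpisodeQC",
    "pillar_template",
    "detect_pillars",
    "build_reference_lattice",
    "track_deflections",
    "classify_contact",
    "segment_worm",
    "qc_episode",
]

_EDGE_WIDTH_PX = 2.0  # must match the renderer's pillar edge profile
_MIN_CORRELATION = 0.5  # NCC peak below this counts as a failed detection


# ---------------------------------------------------------------------------
# Data containers


@dataclass
class PillarTracks:
    """Deflection tracks for all pillars of one episode.

    ``displacement_um`` is ``(n_frames, n_pillars, 2)`` with NaN marking
    frames where a pillar could not be localized; ``confidence`` holds the
    NCC peak value (0 for missing).  ``contact`` is filled by
    :func:`classify_contact` and is ``None`` until then.
    """

    rest_centers_um: np.ndarray  # (P, 2)
    displacement_um: np.ndarray  # (T, P, 2)
    confidence: np.ndarray  # (T, P)
    pixel_size_um_per_px: float
    contact: np.ndarray | None = None  # (T, P) bool

    @property
    def n_frames(self) -> int:
        return self.displacement_um.shape[0]

    @property
    def n_pillars(self) -> int:
        return self.displacement_um.shape[1]

    @property
    def deflection_magnitude_um(self) -> np.ndarray:
        """(T, P) Euclidean deflection magnitudes (NaN where missing)."""
        return np.linalg.norm(self.displacement_um, axis=-1)

    def permuted(self, order: np.ndarray) -> "PillarTracks":
        """Relabel pillars; displacement values are untouched."""
        order = np.asarray(order)
        return PillarTracks(
            rest_centers_um=self.rest_centers_um[order],
            displacement_um=self.displacement_um[:, order],
            confidence=self.confidence[:, order],
            pixel_size_um_per_px=self.pixel_size_um_per_px,
            contact=None if self.contact is None else self.contact[:, order],
        )

    def to_dataframe(self):
        import pandas as pd

        t_idx, p_idx = np.meshgrid(
            np.arange(self.n_frames), np.arange(self.n_pillars), indexing="ij"
        )
        contact = (
            np.zeros((self.n_frames, self.n_pillars), dtype=int)
            if self.contact is None
            else self.contact.astype(int)
        )
        return pd.DataFrame(
            {
                "pillar_id": p_idx.ravel(),
                "frame": t_idx.ravel(),
                "x_um": np.tile(self.rest_centers_um[:, 0], self.n_frames),
                "y_um": np.tile(self.rest_centers_um[:, 1], self.n_frames),
                "dx_um": self.displacement_um[..., 0].ravel(),
                "dy_um": self.displacement_um[..., 1].ravel(),
                "contact": contact.ravel(),
                "confidence": self.confidence.ravel(),
            }
        )


@dataclass(frozen=True)
class EpisodeQC:
    """Episode-level quality control verdict."""

    processed: bool
    failure_reason: str | None  # None | "processing-failure" | "stationary"
    motion_score_um: float | None  # mean per-frame worm centroid displacement

    def __post_init__(self) -> None:
        if self.processed and self.failure_reason not in (None, "stationary"):
            raise ValueError("failure reason set on a processed episode")
        if not self.processed and self.failure_reason is None:
            raise ValueError("unprocessed episode must carry a failure reason")

    @property
    def usable_for_strength(self) -> bool:
        return self.processed and self.failure_reason is None


# ---------------------------------------------------------------------------
# Detection


def pillar_template(radius_px: float, margin_px: int = 3) -> np.ndarray:
    """Soft-edged dark disk on a bright background, matching the optics."""
    half = int(np.ceil(radius_px)) + margin_px
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    dist = np.hypot(xx, yy)
    cov = np.clip((radius_px + 0.5 * _EDGE_WIDTH_PX - dist) / _EDGE_WIDTH_PX, 0.0, 1.0)
    return 1.0 - cov  # dark disk (0) on bright (1)


def _quadratic_peak(corr: np.ndarray, iy: int, ix: int) -> tuple[float, float]:
    """Sub-pixel refinement of an NCC maximum by separable parabola fit."""

    def offset(cm, c0, cp):
        denom = cm - 2.0 * c0 + cp
        if denom >= 0:  # not a proper maximum; keep integer position
            return 0.0
        return float(np.clip(0.5 * (cm - cp) / denom, -0.5, 0.5))

    dy = dx = 0.0
    if 0 < iy < corr.shape[0] - 1:
        dy = offset(corr[iy - 1, ix], corr[iy, ix], corr[iy + 1, ix])
    if 0 < ix < corr.shape[1] - 1:
        dx = offset(corr[iy, ix - 1], corr[iy, ix], corr[iy, ix + 1])
    return iy + dy, ix + dx


def _is_dark_disk(frame: np.ndarray, cx: float, cy: float, radius_px: float,
                  min_relative_depth: float = 0.35) -> bool:
    """True when the disk core is markedly darker than its surround.

    Normalized correlation is contrast-invariant, so any disk-shaped feature
    (e.g. the worm's rounded head) can correlate with the pillar template;
    pillars are distinguished by being the darkest features in the frame.
    """
    h, w = frame.shape
    half = int(np.ceil(1.8 * radius_px))
    x0, x1 = max(int(cx) - half, 0), min(int(cx) + half + 1, w)
    y0, y1 = max(int(cy) - half, 0), min(int(cy) + half + 1, h)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - cx, yy - cy)
    core = frame[y0:y1, x0:x1][dist <= 0.5 * radius_px]
    ring = frame[y0:y1, x0:x1][(dist > 1.2 * radius_px) & (dist <= 1.8 * radius_px)]
    if core.size == 0 or ring.size == 0:
        return False
    ring_mean = float(ring.mean())
    if ring_mean <= 0:
        return False
    return float(core.mean()) < (1.0 - min_relative_depth) * ring_mean


def detect_pillars(
    frame: np.ndarray,
    expected_diameter_px: float,
    min_correlation: float = _MIN_CORRELATION,
) -> np.ndarray:
    """Sub-pixel centers (x, y in px) of circular pillars in one frame.

    Correlation peaks are additionally required to be dark relative to their
    surround (see :func:`_is_dark_disk`), which rejects bright or mid-gray
    circular features such as the worm's head cap.  Centers are sorted
    row-major by rounded position so repeated calls on the same frame
    enumerate pillars deterministically.  An image without circular features
    yields an empty ``(0, 2)`` array.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale frame, got shape {frame.shape}")
    lo, hi = 3.0, min(frame.shape) / 2.0
    if not (lo <= expected_diameter_px <= hi):
        raise ValueError(
            f"expected diameter {expected_diameter_px} px outside [{lo}, {hi}]"
        )
    tmpl = pillar_template(0.5 * expected_diameter_px)
    corr = match_template(frame.astype(float), tmpl, pad_input=True)
    peaks = peak_local_max(
        corr,
        min_distance=max(int(round(expected_diameter_px / 2)), 1),
        threshold_abs=min_correlation,
        exclude_border=False,
    )
    fframe = frame.astype(float)
    centers = []
    for iy, ix in peaks:
        ry, rx = _quadratic_peak(corr, iy, ix)
        if _is_dark_disk(fframe, rx, ry, 0.5 * expected_diameter_px):
            centers.append((rx, ry))
    if not centers:
        return np.empty((0, 2))
    out = np.array(centers, dtype=float)
    order = np.lexsort((np.round(out[:, 0]), np.round(out[:, 1])))
    return out[order]


def _sliding_sums(windows: np.ndarray, t: int) -> tuple[np.ndarray, np.ndarray]:
    """Sliding t x t window sums of W and W^2 via integral images (batched)."""

    def integral(a):
        c = np.cumsum(np.cumsum(a, axis=-2), axis=-1)
        c = np.pad(c, ((0, 0), (1, 0), (1, 0)))
        return c

    w = windows
    i1 = integral(w)
    i2 = integral(w * w)

    def box(i):
        return i[:, t:, t:] - i[:, :-t, t:] - i[:, t:, :-t] + i[:, :-t, :-t]

    return box(i1), box(i2)


def _batched_ncc(windows: np.ndarray, tmpl: np.ndarray, tmpl_fft=None, fshape=None):
    """Normalized cross-correlation of N same-size windows with one template.

    Returns the valid-mode correlation maps ``(N, S-t+1, S-t+1)``.  Passing a
    precomputed ``(tmpl_fft, fshape)`` pair (see :func:`_prepare_template_fft`)
    amortizes the template transform across frames.
    """
    from scipy import fft as sfft

    n_win, s, _ = windows.shape
    t = tmpl.shape[0]
    if tmpl_fft is None:
        tmpl_fft, fshape = _prepare_template_fft(tmpl, s)
    wf = sfft.rfft2(windows, fshape, axes=(-2, -1))
    cross = sfft.irfft2(wf * tmpl_fft, fshape, axes=(-2, -1))
    cross = cross[:, t - 1 : s, t - 1 : s]
    s1, s2 = _sliding_sums(windows, t)
    n = t * t
    t0 = tmpl - tmpl.mean()
    ssd_t = float((t0 * t0).sum())
    var_w = np.maximum(s2 - s1 * s1 / n, 0.0)
    denom = np.sqrt(var_w * ssd_t)
    with np.errstate(divide="ignore", invalid="ignore"):
        ncc = np.where(denom > 1e-12, cross / denom, 0.0)
    return ncc


def _prepare_template_fft(tmpl: np.ndarray, window_size: int):
    from scipy import fft as sfft

    t = tmpl.shape[0]
    fshape = tuple(sfft.next_fast_len(window_size + t - 1) for _ in range(2))
    t0 = tmpl - tmpl.mean()
    return sfft.rfft2(t0[::-1, ::-1], fshape), fshape


def _localize_in_window(
    frame: np.ndarray,
    tmpl: np.ndarray,
    cx_px: float,
    cy_px: float,
    search_px: float,
) -> tuple[float, float, float]:
    """NCC localization of one pillar near (cx, cy); returns (x, y, peak)."""
    h, w = frame.shape
    t_half = tmpl.shape[0] // 2
    half = int(np.ceil(search_px)) + t_half
    x0 = max(int(round(cx_px)) - half, 0)
    x1 = min(int(round(cx_px)) + half + 1, w)
    y0 = max(int(round(cy_px)) - half, 0)
    y1 = min(int(round(cy_px)) + half + 1, h)
    win = frame[y0:y1, x0:x1].astype(float)
    if win.shape[0] < tmpl.shape[0] or win.shape[1] < tmpl.shape[1]:
        return np.nan, np.nan, 0.0
    corr = match_template(win, tmpl, pad_input=False)
    iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
    peak = float(corr[iy, ix])
    if peak < _MIN_CORRELATION:
        return np.nan, np.nan, peak
    ry, rx = _quadratic_peak(corr, iy, ix)
    return x0 + rx + t_half, y0 + ry + t_half, peak


# ---------------------------------------------------------------------------
# Reference lattice and tracking


def build_reference_lattice(
    stack: np.ndarray | None = None,
    arena=None,
    expected_diameter_px: float | None = None,
    pixel_size_um_per_px: float | None = None,
    spacing_um: float | None = None,
) -> np.ndarray:
    """Rest centers (um) either from an arena config or estimated from a stack.

    With ``arena`` supplied its centers are returned verbatim.  Otherwise
    pillars are detected in every frame, matched across frames by nearest
    neighbor within half the lattice spacing, and each rest center is a
    trimmed per-pillar median over the frames where the pillar sits at its
    sub-pixel rest cluster (contacted frames are iteratively trimmed away).
    A pillar displaced in every frame cannot be resolved and raises an error
    naming it.
    """
    if arena is not None:
        return np.asarray(arena.rest_centers_um, dtype=float).copy()
    if stack is None:
        raise ValueError("either a stack or an arena config is required")
    if expected_diameter_px is None or pixel_size_um_per_px is None:
        raise ValueError("stack-based estimation needs diameter and pixel size")

    detections = [detect_pillars(frame, expected_diameter_px) for frame in stack]
    anchor_frame = int(np.argmax([len(d) for d in detections]))
    anchors = list(detections[anchor_frame])
    if len(anchors) == 0:
        raise ValueError("no pillars detected in any frame")
    # merge near-duplicate anchors (spurious peaks resolve to a real pillar)
    merged: list[np.ndarray] = []
    for c in anchors:
        if all(np.linalg.norm(c - m) > expected_diameter_px for m in merged):
            merged.append(c)
    anchors = np.array(merged)
    match_radius_px = (
        0.5 * spacing_um / pixel_size_um_per_px
        if spacing_um is not None
        else 1.5 * expected_diameter_px
    )

    per_pillar: list[list[np.ndarray]] = [[] for _ in anchors]
    for det in detections:
        if len(det) == 0:
            continue
        d2 = np.sum((anchors[:, None, :] - det[None, :, :]) ** 2, axis=-1)
        for p in range(len(anchors)):
            j = int(np.argmin(d2[p]))
            if d2[p, j] <= match_radius_px**2:
                per_pillar[p].append(det[j])

    # a transient spurious anchor (e.g. a worm-edge correlation peak) is
    # matched in few frames; real pillars are matched in most
    support = np.array([len(obs) for obs in per_pillar])
    keep = support >= 0.5 * len(stack)
    if not keep.any():
        raise ValueError("no persistently detected pillar found")
    anchors = anchors[keep]
    per_pillar = [obs for obs, k in zip(per_pillar, keep) if k]

    # A pillar's detections form a tight cluster at rest (sub-pixel noise)
    # plus a spread of displaced positions in contacted frames.  Starting
    # from the overall median, a trimmed median with a shrinking window
    # converges onto the rest cluster even when half the frames are
    # contacted; a pillar with no sub-pixel cluster (contacted throughout)
    # is unresolvable and reported by id.
    refined = []
    for p, obs in enumerate(per_pillar):
        obs = np.array(obs)
        center = np.median(obs, axis=0)
        for window_px in np.geomspace(8.0, 0.75, 8):
            resid = np.linalg.norm(obs - center, axis=1)
            quiet = obs[resid <= window_px]
            if len(quiet) == 0:
                break
            center = np.median(quiet, axis=0)
        resid = np.linalg.norm(obs - center, axis=1)
        quiet = obs[resid <= 0.75]
        if len(quiet) < max(3, 0.05 * len(stack)):
            raise ValueError(
                f"pillar {p} appears contacted in every frame; rest position "
                "unresolvable without an arena config"
            )
        refined.append(np.median(quiet, axis=0))
    return np.array(refined) * pixel_size_um_per_px


def track_deflections(
    stack: np.ndarray,
    rest_centers_um: np.ndarray,
    pixel_size_um_per_px: float,
    pillar_diameter_um: float,
    spacing_um: float | None = None,
) -> PillarTracks:
    """Track every pillar through the stack and report displacements in um.

    Each pillar is localized within a search window centred on its rest
    position (radius half the matching radius, i.e. lattice spacing / 4, so
    neighbouring pillars cannot capture the match).  Unmatched pillars are
    marked missing with zero confidence.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (n_frames, h, w)")
    rest = np.asarray(rest_centers_um, dtype=float)
    px = pixel_size_um_per_px
    radius_px = 0.5 * pillar_diameter_um / px
    tmpl = pillar_template(radius_px)
    if spacing_um is None:
        spacing_um = 3.0 * pillar_diameter_um
    search_px = 0.25 * spacing_um / px

    n_frames, n_pillars = len(stack), len(rest)
    disp = np.full((n_frames, n_pillars, 2), np.nan)
    conf = np.zeros((n_frames, n_pillars))
    rest_px_xy = rest / px

    # same-size search windows around every rest center let the NCC run
    # batched per frame with one precomputed template transform
    t_half = tmpl.shape[0] // 2
    half = int(np.ceil(search_px)) + t_half
    size = 2 * half + 1
    h, w = stack.shape[1:]
    corners = np.round(rest_px_xy).astype(int) - half  # (P, 2) as (x, y)
    in_bounds = (
        (corners[:, 0] >= 0)
        & (corners[:, 1] >= 0)
        & (corners[:, 0] + size <= w)
        & (corners[:, 1] + size <= h)
    )
    batch_idx = np.flatnonzero(in_bounds)
    fallback_idx = np.flatnonzero(~in_bounds)
    tmpl_fft, fshape = _prepare_template_fft(tmpl, size)

    for t in range(n_frames):
        frame = stack[t].astype(float)
        if len(batch_idx):
            windows = np.stack(
                [
                    frame[corners[p, 1] : corners[p, 1] + size,
                          corners[p, 0] : corners[p, 0] + size]
                    for p in batch_idx
                ]
            )
            ncc = _batched_ncc(windows, tmpl, tmpl_fft, fshape)
            for j, p in enumerate(batch_idx):
                iy, ix = np.unravel_index(np.argmax(ncc[j]), ncc[j].shape)
                peak = float(ncc[j, iy, ix])
                if peak < _MIN_CORRELATION:
                    continue
                ry, rx = _quadratic_peak(ncc[j], iy, ix)
                x = corners[p, 0] + rx + t_half
                y = corners[p, 1] + ry + t_half
                dx_um = (x - rest_px_xy[p, 0]) * px
                dy_um = (y - rest_px_xy[p, 1]) * px
                if np.hypot(dx_um, dy_um) > 0.5 * spacing_um:
                    continue  # matched something else; treat as missing
                disp[t, p] = (dx_um, dy_um)
                conf[t, p] = peak
        for p in fallback_idx:
            x, y, peak = _localize_in_window(
                frame, tmpl, rest_px_xy[p, 0], rest_px_xy[p, 1], search_px
            )
            if np.isnan(x):
                continue
            dx_um = (x - rest_px_xy[p, 0]) * px
            dy_um = (y - rest_px_xy[p, 1]) * px
            if np.hypot(dx_um, dy_um) > 0.5 * spacing_um:
                continue
            disp[t, p] = (dx_um, dy_um)
            conf[t, p] = peak
    return PillarTracks(
        rest_centers_um=rest.copy(),
        displacement_um=disp,
        confidence=conf,
        pixel_size_um_per_px=px,
    )


# ---------------------------------------------------------------------------
# Worm segmentation and contact classification


def segment_worm(
    stack: np.ndarray,
    min_area_px: int = 500,
) -> np.ndarray:
    """Binary worm masks for a stack (or a single frame) by 3-class Otsu.

    The middle intensity class is the worm body (pillars are darker, the
    background brighter).  Thin anti-aliased rings around pillar edges fall
    into the middle class too and can touch the worm, so the raw class mask
    is opened with a small disk (removing structures a few pixels thin)
    before keeping the largest connected component per frame.  Returns masks
    of the same leading shape as the input.
    """
    from skimage.filters import threshold_multiotsu

    arr = np.asarray(stack)
    single = arr.ndim == 2
    frames = arr[None] if single else arr
    # threshold on a float copy: integer inputs make multiotsu bin the full
    # integer range, which is pathologically slow for 16-bit frames
    ref = frames[len(frames) // 2].astype(float)
    t_lo, t_hi = threshold_multiotsu(ref, classes=3, nbins=256)
    yy, xx = np.mgrid[-2:3, -2:3]
    disk = (xx**2 + yy**2) <= 4
    masks = np.zeros(frames.shape, dtype=bool)
    for i, frame in enumerate(frames):
        raw = (frame > t_lo) & (frame <= t_hi)
        raw = ndimage.binary_opening(raw, structure=disk)
        labels, n = ndimage.label(raw)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(raw, labels, index=np.arange(1, n + 1))
        if sizes.max() < min_area_px:
            continue
        masks[i] = labels == (int(np.argmax(sizes)) + 1)
    return masks[0] if single else masks


def classify_contact(
    tracks: PillarTracks,
    worm_masks: np.ndarray | None = None,
    pillar_diameter_um: float | None = None,
    k: float = 3.0,
    sigma_noise_um: float | None = None,
    displacement_floor_px: float = 1.0,
) -> PillarTracks:
    """Attach per-(frame, pillar) contact flags to a track set.

    With worm masks available, a pillar is in contact when any worm-mask
    pixel lies within one pillar radius of its rest center (equivalent to
    the center falling inside the mask dilated by d/2).  A pillar pressed
    deep into the worm can occlude every worm pixel in its own
    neighbourhood, so the mask criterion is OR-ed with the displacement
    criterion whenever a noise floor can be estimated from pillars that are
    never mask-contacted; that rescue is floored at ``displacement_floor_px``
    (uncontacted pillars adjacent to the worm carry a localization bias of up
    to ~0.5 px, well above the far-field noise).  Without masks, contact is
    ``|displacement| > k * sigma_noise`` alone, with the noise floor from
    never-displaced pillars; if none exists, pass ``sigma_noise_um``.
    """
    T, P = tracks.n_frames, tracks.n_pillars
    mags = tracks.deflection_magnitude_um
    if worm_masks is not None:
        if pillar_diameter_um is None:
            raise ValueError("mask-based contact needs the pillar diameter")
        px = tracks.pixel_size_um_per_px
        r_px = 0.5 * pillar_diameter_um / px
        half = int(np.ceil(r_px)) + 1
        contact = np.zeros((T, P), dtype=bool)
        h, w = worm_masks.shape[-2:]
        centers_px = tracks.rest_centers_um / px
        for p in range(P):
            cx, cy = centers_px[p]
            x0, x1 = max(int(cx) - half, 0), min(int(cx) + half + 1, w)
            y0, y1 = max(int(cy) - half, 0), min(int(cy) + half + 1, h)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            near = np.hypot(xx - cx, yy - cy) <= r_px
            contact[:, p] = (worm_masks[:, y0:y1, x0:x1] & near).any(axis=(1, 2))
        if sigma_noise_um is None:
            quiet = ~contact.any(axis=0)
            if quiet.any():
                comps = tracks.displacement_um[:, quiet, :]
                if np.isfinite(comps).any():
                    sigma_noise_um = float(np.nanstd(comps))
        if sigma_noise_um is not None and sigma_noise_um > 0:
            threshold = max(k * sigma_noise_um, displacement_floor_px * px)
            contact |= np.nan_to_num(mags, nan=0.0) > threshold
    else:
        if sigma_noise_um is None:
            # localization noise is sub-pixel by construction, so only
            # pillars that never move beyond a pixel-scale ceiling can serve
            # as noise-floor references
            ceiling = 0.75 * tracks.pixel_size_um_per_px
            finite = np.nan_to_num(mags, nan=0.0)
            quiet = np.nanmax(finite, axis=0) <= ceiling
            if not quiet.any():
                raise ValueError(
                    "no never-contacted pillar available to estimate the noise "
                    "floor; pass sigma_noise_um explicitly"
                )
            comps = tracks.displacement_um[:, quiet, :]
            sigma_noise_um = float(np.nanstd(comps))
        contact = np.nan_to_num(mags, nan=0.0) > k * sigma_noise_um
    return replace(tracks, contact=contact)


# ---------------------------------------------------------------------------
# Episode QC


def qc_episode(
    stack,
    pixel_size_um_per_px: float,
    stationary_threshold_um: float = 1.5,
    worm_masks: np.ndarray | None = None,
    closing_radius_px: float = 0.0,
) -> EpisodeQC:
    """Episode-level QC: processing success and worm-motion screening.

    ``stack`` may be an array or a path to a TIFF stack; an unreadable file
    yields a processing-failure QC record instead of an exception.  The
    motion score is the mean per-frame displacement of the worm-mask
    centroid in um; below ``stationary_threshold_um`` the episode is flagged
    stationary (and excluded from strength aggregation downstream).

    Pillars occlude the worm and move with their deflections, so even a
    stationary worm shows residual centroid jitter well below a micron per
    frame; the default threshold sits above that floor.  For noisier data,
    ``closing_radius_px > 0`` morphologically closes each mask with a disk
    of that radius first, removing pillar-shaped bites at extra cost.
    """
    if not isinstance(stack, np.ndarray):
        from .fileio import read_image_stack

        try:
            stack, _ = read_image_stack(stack)
        except Exception:
            return EpisodeQC(False, "processing-failure", None)
    try:
        if worm_masks is None:
            worm_masks = segment_worm(stack)
        centroids = []
        for mask in worm_masks:
            if not mask.any():
                centroids.append((np.nan, np.nan))
                continue
            if closing_radius_px > 0:
                dilated = (
                    ndimage.distance_transform_edt(~mask) <= closing_radius_px
                )
                mask = ndimage.distance_transform_edt(dilated) > closing_radius_px
            cy, cx = ndimage.center_of_mass(mask)
            centroids.append((cx, cy))
        centroids = np.array(centroids) * pixel_size_um_per_px
        steps = np.linalg.norm(np.diff(centroids, axis=0), axis=1)
        if not np.isfinite(steps).any():
            return EpisodeQC(False, "processing-failure", None)
        motion = float(np.nanmean(steps))
    except Exception:
        return EpisodeQC(False, "processing-failure", None)
    if motion < stationary_threshold_um:
        return EpisodeQC(True, "stationary", motion)
    return EpisodeQC(True, None, motion)
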