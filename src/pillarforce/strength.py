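"""The per-worm strength statistic f95 and its covariates.

A worm's strength over an imaging episode is summarized by the 95th
percentile of the per-frame maximal pillar forces (``f95``), a robust proxy
for maximal voluntary force: the maximum a worm exerts somewhere in the arena
in each frame, with the top 5% trimmed to guard against tracking outliers.
Frames in which the worm touches no pillar carry no strength information and
are omitted rather than scored zero — zero-padding would make f95 measure
contact frequency, not strength.

Body diameter is the one morphological covariate that strongly affects
strength, so it is measured alongside (median cross-sectional width of the
worm mask, perpendicular to the midline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .stats import WelchResult, welch_ttest

logger = logging.getLogger(__name__)

__all__ = [
    "StrengthResult",
    "frame_max_forces",
    "f95",
    "measure_diameter",
    "compare_groups",
    "cohort_summary",
]

DEFAULT_MIN_FRAMES = 20


@dataclass
class StrengthResult:
    """Strength measurement of one worm-episode.

    ``f95_uN`` is ``None`` for episodes excluded by QC; excluded episodes
    never enter cohort aggregation.
    """

    worm_id: str
    strain: str = ""
    treatment: str = "C"
    day: int = 1
    frame_max_uN: np.ndarray = field(default_factory=lambda: np.array([]))
    n_frames_used: int = 0
    f95_uN: float | None = None
    diameter_um: float | None = None
    qc_status: str = "ok"  # ok | stationary | processing-failure

    def __post_init__(self) -> None:
        if self.f95_uN is not None and self.qc_status != "ok":
            raise ValueError("excluded episodes carry no f95")
        if self.f95_uN is not None and len(self.frame_max_uN):
            lo, hi = float(np.min(self.frame_max_uN)), float(np.max(self.frame_max_uN))
            if not (lo <= self.f95_uN <= hi):
                raise ValueError("f95 must lie within the per-frame maxima range")


def frame_max_forces(force_uN: np.ndarray, contact: np.ndarray) -> np.ndarray:
    """Per-frame maximum force over contacted pillars.

    ``force_uN`` and ``contact`` are ``(n_frames, n_pillars)``; frames with no
    contacted pillar (or only missing forces) are omitted from the series and
    their count logged.  NaN forces (missing detections) never contribute.
    """
    force = np.asarray(force_uN, dtype=float)
    contact = np.asarray(contact, dtype=bool)
    if force.shape != contact.shape:
        raise ValueError("force and contact tables must have the same shape")
    usable = contact & np.isfinite(force)
    has_contact = usable.any(axis=1)
    n_omitted = int((~has_contact).sum())
    if n_omitted:
        logger.info("omitting %d frame(s) with no pillar contact", n_omitted)
    masked = np.where(usable, force, -np.inf)
    return masked[has_contact].max(axis=1)


def f95(
    series,
    level: float = 95.0,
    method: str = "linear",
    min_frames: int = DEFAULT_MIN_FRAMES,
) -> float:
    """Percentile of the per-frame maxima series (default: 95th).

    ``method='linear'`` interpolates between the closest order statistics
    (rank ``h = (n-1) * level/100``); ``method='nearest'`` returns the
    nearest-rank order statistic (smallest value with at least ``level`` % of
    the data at or below it).  Series shorter than ``min_frames`` cannot give
    a stable extreme percentile and raise.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if len(x) < max(min_frames, 1):
        raise ValueError(
            f"need at least {min_frames} frames with contact for f95, got {len(x)}"
        )
    if not (0 <= level <= 100):
        raise ValueError("percentile level must lie in [0, 100]")
    xs = np.sort(x)
    n = len(xs)
    if method == "linear":
        h = (n - 1) * level / 100.0
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        frac = h - lo
        return float(xs[lo] + frac * (xs[hi] - xs[lo]))
    if method == "nearest":
        if level == 0:
            return float(xs[0])
        rank = int(np.ceil(level / 100.0 * n))
        return float(xs[rank - 1])
    raise ValueError(f"unknown percentile method {method!r}")


# ---------------------------------------------------------------------------
# Diameter


def _mask_widths(mask: np.ndarray, max_width_px: float = 200.0) -> np.ndarray:
    """Cross-sectional widths (px) of a binary tube mask.

    The midline is the morphological skeleton; at regularly sampled skeleton
    points the local tangent is estimated from nearby skeleton pixels and the
    mask is profiled along the perpendicular with sub-pixel bisection of the
    0.5 crossing on each side.
    """
    from skimage.morphology import skeletonize

    skel = skeletonize(mask)
    pts = np.column_stack(np.nonzero(skel))  # (k, 2) as (row, col)
    if len(pts) < 3:
        return np.array([])
    fmask = mask.astype(float)

    def interp(coords_rc):
        return ndimage.map_coordinates(fmask, coords_rc, order=1, mode="constant")

    widths = []
    step = max(len(pts) // 40, 1)
    for i in range(0, len(pts), step):
        p = pts[i]
        near = pts[np.sum((pts - p) ** 2, axis=1) <= 49]  # radius 7 px
        if len(near) < 3:
            continue
        centered = near - near.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        tangent = vt[0]
        normal = np.array([-tangent[1], tangent[0]])

        def crossing(direction):
            t_lo, t_hi = 0.0, 1.0
            # march outward until outside the mask
            while t_hi < max_width_px:
                c = p + t_hi * direction
                if interp(c.reshape(2, 1))[0] < 0.5:
                    break
                t_lo = t_hi
                t_hi += 1.0
            else:
                return np.nan
            for _ in range(20):  # bisection to sub-pixel
                mid = 0.5 * (t_lo + t_hi)
                c = p + mid * direction
                if interp(c.reshape(2, 1))[0] >= 0.5:
                    t_lo = mid
                else:
                    t_hi = mid
            return 0.5 * (t_lo + t_hi)

        t_plus = crossing(normal)
        t_minus = crossing(-normal)
        if np.isfinite(t_plus) and np.isfinite(t_minus):
            widths.append(t_plus + t_minus)
    return np.asarray(widths)


def measure_diameter(
    worm_masks: np.ndarray,
    pixel_size_um_per_px: float,
    n_sample_frames: int = 7,
) -> float:
    """Worm body diameter in um from per-frame binary masks.

    Per sampled frame the diameter is the median cross-sectional width of the
    mask perpendicular to its midline; the episode diameter is the median
    over sampled frames, scaled by the pixel size.
    """
    masks = np.asarray(worm_masks)
    if masks.ndim == 2:
        masks = masks[None]
    nonempty = [m for m in masks if m.any()]
    if not nonempty:
        raise ValueError("no non-empty worm mask available")
    idx = np.unique(np.linspace(0, len(nonempty) - 1, n_sample_frames).astype(int))
    per_frame = []
    for i in idx:
        w = _mask_widths(nonempty[i])
        if len(w):
            per_frame.append(np.median(w))
    if not per_frame:
        raise ValueError("could not measure any cross-sectional width")
    return float(np.median(per_frame) * pixel_size_um_per_px)


# ---------------------------------------------------------------------------
# Group comparison and cohort tables


def compare_groups(cohort_a, cohort_b) -> WelchResult:
    """Welch two-sample t-test between two cohorts of per-worm f95 values.

    Each worm contributes one independent sample.  Accepts sequences of
    floats or of :class:`StrengthResult` (excluded episodes are dropped).
    """

    def values(cohort):
        vals = []
        for item in cohort:
            if isinstance(item, StrengthResult):
                if item.f95_uN is not None:
                    vals.append(item.f95_uN)
            else:
                vals.append(float(item))
        return np.asarray(vals)

    return welch_ttest(values(cohort_a), values(cohort_b))


def cohort_summary(results) -> "pd.DataFrame":
    """Per-(strain, treatment, day) table of mean, s.e.m. and n.

    Mirrors the bar-plot tabulation of a strength study: three sampling days
    by five treatment codes (C, M1, M2, P1, P2) per strain.
    """
    import pandas as pd

    rows = [
        {
            "worm_id": r.worm_id,
            "strain": r.strain,
            "treatment": r.treatment,
            "day": r.day,
            "f95_uN": r.f95_uN,
            "diameter_um": r.diameter_um,
        }
        for r in results
        if r.f95_uN is not None
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    grouped = (
        df.groupby(["strain", "treatment", "day"])["f95_uN"]
        .agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)), n="count")
        .reset_index()
    )
    return grouped
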