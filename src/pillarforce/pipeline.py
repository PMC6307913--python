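"""End-to-end orchestration: simulate episodes, analyze them, emit tables.

``run_pipeline`` executes synthetic generation and/or the analysis chain
(track -> contact -> force -> f95 -> diameter) under a single
:class:`~pillarforce.config.RunConfig`.  Identical config + seed gives
byte-identical numerical outputs; a manifest records the config hash, seeds,
file inventory and per-stage log.  Episodes that fail to process are
quarantined as QC records, never silently dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import fileio, strength, tracking
from .beam import deflection_to_force
from .config import RunConfig, save_config
from .synthetic import ForceProgram, WormKinematics, render_episode

logger = logging.getLogger(__name__)

__all__ = ["EpisodeAnalysis", "analyze_episode", "run_pipeline"]


@dataclass
class EpisodeAnalysis:
    """Everything the analysis chain produces for one episode."""

    tracks: tracking.PillarTracks | None
    qc: tracking.EpisodeQC
    frame_max_uN: np.ndarray
    f95_uN: float | None
    diameter_um: float | None


def analyze_episode(
    stack: np.ndarray,
    arena,
    config: RunConfig | None = None,
    measure_diam: bool = True,
) -> EpisodeAnalysis:
    """Run the measurement chain on one image stack with a known arena.

    Worm masks are segmented per frame; contact is mask-based; deflection
    magnitudes convert to forces through the arena's beam compliance; f95 is
    computed over per-frame maxima of contacted-pillar forces.
    """
    config = config or RunConfig()
    ap = config.analysis
    px = arena.pixel_size_um_per_px

    try:
        masks = tracking.segment_worm(stack)
    except Exception:
        masks = None
    qc = tracking.qc_episode(
        stack, px, stationary_threshold_um=ap.stationary_threshold_um,
        worm_masks=masks,
    )
    if not qc.processed:
        return EpisodeAnalysis(None, qc, np.array([]), None, None)
    rest = tracking.build_reference_lattice(arena=arena)
    tracks = tracking.track_deflections(
        stack,
        rest,
        px,
        pillar_diameter_um=arena.pillar_diameter_um,
        spacing_um=arena.lattice_spacing_um,
    )
    tracks = tracking.classify_contact(
        tracks,
        worm_masks=masks,
        pillar_diameter_um=arena.pillar_diameter_um,
        k=ap.contact_k,
    )
    # missing detections carry NaN deflection and stay NaN as forces;
    # frame_max_forces never lets them contribute
    forces = deflection_to_force(tracks.deflection_magnitude_um, arena.beam_spec)
    series = strength.frame_max_forces(forces, tracks.contact)

    diameter = None
    if measure_diam:
        try:
            diameter = strength.measure_diameter(masks, px)
        except ValueError:
            diameter = None

    f95_val = None
    if qc.usable_for_strength and len(series) >= ap.min_frames:
        f95_val = strength.f95(
            series,
            level=ap.percentile_level,
            method=ap.percentile_method,
            min_frames=ap.min_frames,
        )
    return EpisodeAnalysis(tracks, qc, series, f95_val, diameter)


def run_pipeline(config: RunConfig, mode: str = "both") -> dict:
    """Execute a run in ``simulate``, ``analyze`` or ``both`` mode.

    simulate: render ``n_episodes`` episodes (TIFF + ledger CSV + config).
    analyze: read every episode TIFF in the output directory and produce the
    per-worm strength table plus QC records.  Episodes whose outputs already
    exist are skipped, so interrupted runs resume at the next episode.
    """
    if mode not in ("simulate", "analyze", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    out = Path(config.out_dir)
    manifest: dict = {
        "config_hash": config.hash,
        "seed": config.seed,
        "mode": mode,
        "files": {},
        "stages": [],
    }
    arena = config.make_arena()

    if mode in ("simulate", "both"):
        out.mkdir(parents=True, exist_ok=True)
        save_config(config, out / "config.yaml")
        root = np.random.SeedSequence([config.seed, 707])
        episode_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                         root.spawn(config.n_episodes)]
        for i, ep_seed in enumerate(episode_seeds):
            name = f"episode_{i:03d}"
            if (out / f"{name}.tiff").exists():
                manifest["stages"].append(
                    {"stage": "simulate", "episode": name, "event": "resume-skip"}
                )
                continue
            spec = config.make_episode_spec(ep_seed)
            worm = WormKinematics(diameter_um=config.worm_diameter_um)
            forces = ForceProgram(f_max_uN=config.f_max_uN)
            stack, ledger = render_episode(arena, spec, worm, forces)
            inv = fileio.write_episode(out, name, stack, ledger, arena, spec)
            manifest["files"][name] = inv
            manifest["stages"].append(
                {"stage": "simulate", "episode": name, "event": "written",
                 "seed": ep_seed}
            )

    if mode in ("analyze", "both"):
        if not out.is_dir():
            raise FileNotFoundError(f"input directory {out} does not exist")
        tiffs = sorted(out.glob("episode_*.tiff"))
        if not tiffs:
            raise FileNotFoundError(f"no episode TIFFs found in {out}")
        rows = []
        qc_records = {}
        for tiff in tiffs:
            name = tiff.stem
            try:
                stack, _ = fileio.read_image_stack(tiff, config.frame_rate_hz)
                res = analyze_episode(stack, arena, config)
            except Exception as exc:  # corrupt inputs are quarantined
                logger.warning("episode %s failed: %s", name, exc)
                qc_records[name] = {
                    "processed": False,
                    "failure_reason": "processing-failure",
                    "motion_score_um": None,
                }
                manifest["stages"].append(
                    {"stage": "analyze", "episode": name, "event": "quarantined"}
                )
                continue
            qc_records[name] = {
                "processed": res.qc.processed,
                "failure_reason": res.qc.failure_reason,
                "motion_score_um": res.qc.motion_score_um,
            }
            rows.append(
                {
                    "worm_id": name,
                    "f95_uN": res.f95_uN,
                    "diameter_um": res.diameter_um,
                    "n_frames_used": len(res.frame_max_uN),
                    "qc": res.qc.failure_reason or "ok",
                }
            )
            manifest["stages"].append(
                {"stage": "analyze", "episode": name, "event": "analyzed",
                 "f95_uN": res.f95_uN}
            )
        table = pd.DataFrame(rows)
        table_path = out / "strength_results.csv"
        table.to_csv(table_path, index=False)
        (out / "qc.json").write_text(json.dumps(qc_records, indent=2))
        manifest["files"]["strength_results"] = str(table_path)
        manifest["files"]["qc"] = str(out / "qc.json")

    (out / "manifest.json").parent.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
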