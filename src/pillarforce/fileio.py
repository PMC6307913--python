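"""Reading and writing the pipeline's standard file formats.

Image stacks are multi-page grayscale TIFF (8- or 16-bit); ledgers and track
tables are CSV; arena/episode configuration is flat YAML.  Frame rate is
never trusted from file tags — it always comes from the run configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = [
    "read_image_stack",
    "write_image_stack",
    "write_episode",
    "read_ledger_csv",
]


def read_image_stack(path, frame_rate_hz: float | None = None):
    """Read a multi-page grayscale TIFF stack.

    Returns ``(stack, meta)`` with ``stack`` of shape (n_frames, h, w) and
    ``meta`` holding page count, shape, dtype and — when ``frame_rate_hz``
    is supplied — the episode duration in seconds.  RGB pages, pages of
    differing shape, and unreadable files raise a format error naming the
    offending page.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            pages = tif.pages
            n = len(pages)
            if n == 0:
                raise ValueError(f"{path}: empty TIFF")
            frames = []
            shape0 = None
            for i in range(n):
                page = pages[i]
                arr = page.asarray()
                if arr.ndim != 2:
                    raise ValueError(
                        f"{path}: page {i} is not grayscale (shape {arr.shape})"
                    )
                if shape0 is None:
                    shape0 = arr.shape
                elif arr.shape != shape0:
                    raise ValueError(
                        f"{path}: page {i} shape {arr.shape} differs from "
                        f"page 0 shape {shape0}"
                    )
                frames.append(arr)
    except (OSError, tifffile.TiffFileError) as exc:
        raise ValueError(f"{path}: unreadable TIFF ({exc})") from exc
    stack = np.stack(frames)
    if stack.dtype not in (np.uint8, np.uint16):
        raise ValueError(f"{path}: expected 8- or 16-bit grayscale, got {stack.dtype}")
    meta = {
        "path": str(path),
        "n_frames": len(stack),
        "shape": shape0,
        "dtype": str(stack.dtype),
    }
    if frame_rate_hz:
        meta["duration_s"] = len(stack) / frame_rate_hz
        meta["too_short_for_f95"] = len(stack) < 20
    return stack, meta


def write_image_stack(path, stack: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(stack))


def _arena_to_dict(arena) -> dict:
    return {
        "pillar_diameter_um": arena.pillar_diameter_um,
        "pillar_height_um": arena.pillar_height_um,
        "contact_height_um": arena.contact_height_um,
        "lattice_spacing_um": arena.lattice_spacing_um,
        "lattice_kind": arena.lattice_kind,
        "youngs_modulus_kPa": arena.youngs_modulus_kPa,
        "poisson_ratio": arena.poisson_ratio,
        "pixel_size_um_per_px": arena.pixel_size_um_per_px,
        "image_shape_px": list(arena.image_shape_px),
        "rest_centers_um": [list(map(float, c)) for c in arena.rest_centers_um],
    }


def arena_from_dict(d: dict):
    from .synthetic import PillarArena

    d = dict(d)
    d["image_shape_px"] = tuple(d["image_shape_px"])
    d["rest_centers_um"] = np.asarray(d["rest_centers_um"], dtype=float)
    return PillarArena(**d)


def write_episode(directory, name: str, stack, ledger, arena, episode) -> dict:
    """Write one episode: TIFF stack, ledger CSV and YAML config.

    Returns the file inventory (paths keyed by kind).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tiff_path = directory / f"{name}.tiff"
    ledger_path = directory / f"{name}_ledger.csv"
    config_path = directory / f"{name}_config.yaml"
    write_image_stack(tiff_path, stack)
    ledger.to_dataframe().to_csv(ledger_path, index=False)
    cfg = {
        "arena": _arena_to_dict(arena),
        "episode": {
            "duration_s": episode.duration_s,
            "frame_rate_hz": episode.frame_rate_hz,
            "noise_sigma": episode.noise_sigma,
            "illumination_gradient": episode.illumination_gradient,
            "seed": episode.seed,
        },
        "worm_diameter_um": ledger.worm_diameter_um,
    }
    config_path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return {"tiff": str(tiff_path), "ledger": str(ledger_path), "config": str(config_path)}


def read_ledger_csv(path):
    import pandas as pd

    return pd.read_csv(path)
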