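"""Run configuration: one flat YAML file drives a reproducible run.

Every analysis threshold and every generator parameter lives here; all
randomness flows from the single ``seed``.  The config hash covers exactly
the analysed fields, so it changes iff any of them changes, and each output
directory receives a copy of the resolved config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

__all__ = ["AnalysisParams", "CohortDesign", "RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class AnalysisParams:
    contact_k: float = 3.0
    min_frames: int = 20
    percentile_level: float = 95.0
    percentile_method: str = "linear"  # linear | nearest
    hysteresis_frac: float = 0.2
    stationary_threshold_um: float = 1.5

    def __post_init__(self) -> None:
        if not (0 <= self.hysteresis_frac < 1):
            raise ValueError("hysteresis fraction must lie in [0, 1)")
        if not (0 <= self.percentile_level <= 100):
            raise ValueError("percentile level must lie in [0, 100]")
        if self.percentile_method not in ("linear", "nearest"):
            raise ValueError("percentile method must be 'linear' or 'nearest'")
        if self.min_frames < 1 or self.contact_k < 0:
            raise ValueError("invalid analysis thresholds")


@dataclass(frozen=True)
class CohortDesign:
    strains: tuple[str, ...] = ("WT", "dys-1(cx18)", "dys-1(eg33)")
    treatments: tuple[str, ...] = ("C", "M1", "M2", "P1", "P2")
    days: tuple[int, ...] = (1, 3, 5)


@dataclass(frozen=True)
class RunConfig:
    # arena geometry / material
    n_rows: int = 4
    n_cols: int = 4
    lattice_spacing_um: float = 120.0
    lattice_kind: str = "square"
    pillar_diameter_um: float = 40.0
    pillar_height_um: float = 87.0
    contact_height_um: float = 40.0
    youngs_modulus_kPa: float = 250.0
    poisson_ratio: float = 0.49
    pixel_size_um_per_px: float = 1.0
    jitter_frac: float = 0.0
    # episode acquisition
    duration_s: float = 45.0
    frame_rate_hz: float = 5.0
    noise_sigma: float = 0.02
    illumination_gradient: float = 0.05
    # worm + force program
    worm_diameter_um: float = 60.0
    f_max_uN: float = 12.0
    # analysis
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    cohort: CohortDesign = field(default_factory=CohortDesign)
    # run control
    n_episodes: int = 5
    seed: int = 0
    out_dir: str = "runs/default"

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def hash(self) -> str:
        """Hash over all analysed fields (excludes only the output path)."""
        d = self.to_dict()
        d.pop("out_dir")
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def make_arena(self):
        from .synthetic import gen_arena

        return gen_arena(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            lattice_spacing_um=self.lattice_spacing_um,
            lattice_kind=self.lattice_kind,
            pillar_diameter_um=self.pillar_diameter_um,
            pillar_height_um=self.pillar_height_um,
            contact_height_um=self.contact_height_um,
            youngs_modulus_kPa=self.youngs_modulus_kPa,
            poisson_ratio=self.poisson_ratio,
            pixel_size_um_per_px=self.pixel_size_um_per_px,
            jitter_frac=self.jitter_frac,
            seed=self.seed,
        )

    def make_episode_spec(self, seed: int):
        from .synthetic import EpisodeSpec

        return EpisodeSpec(
            duration_s=self.duration_s,
            frame_rate_hz=self.frame_rate_hz,
            noise_sigma=self.noise_sigma,
            illumination_gradient=self.illumination_gradient,
            seed=seed,
        )


def load_config(path, **overrides) -> RunConfig:
    """Load a YAML run config; keyword overrides win over file values."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update(overrides)
    analysis = AnalysisParams(**raw.pop("analysis", {}))
    cohort_raw = raw.pop("cohort", {})
    cohort = CohortDesign(
        **{k: tuple(v) for k, v in cohort_raw.items()}
    )
    return RunConfig(analysis=analysis, cohort=cohort, **raw)


def save_config(config: RunConfig, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
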