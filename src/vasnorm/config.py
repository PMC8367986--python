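"""Run configuration: one YAML file governs every pipeline stage.

The config is a plain nested mapping with one section per stage; values are
validated against their stated domains at load time so a bad run fails
before any computation.  All randomness flows from the single ``seed`` via
named per-stage substreams, and the config round-trips losslessly through
YAML so a run can always be reproduced from its provenance record.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Invalid configuration value."""


@dataclass
class VesselStageConfig:
    image_shape: tuple[int, int] = (512, 512)
    pixel_pitch: float = 0.32
    n_vessels: int = 20
    radius_range: tuple[float, float] = (3.0, 8.0)
    pericyte_fraction: float = 0.5
    noise_sd: float = 2.0
    suppression_radius_px: float = 10.0
    adjacency_px: float = 10.0
    min_votes: int = 3
    n_annotators: int = 4
    annotator_fp_rate: float = 0.1
    annotator_fn_rate: float = 0.1


@dataclass
class DceStageConfig:
    grid_shape: tuple[int, int, int] = (8, 8, 4)
    n_frames: int = 50
    frame_time: float = 9.0
    injection_frame: int = 11
    iauc_window_s: float = 90.0
    core_fraction: float = 0.2
    peak_concentration_mm: float = 0.5
    noise_sd: float = 0.0


@dataclass
class GrowthStageConfig:
    endpoint_volume: float = 400.0
    control_group: str = "control"
    growth_rate: float = 0.15
    arrest_days: float = 10.0
    n_control: int = 7
    n_treated: int = 10
    calliper_cv: float = 0.05
    measurement_interval: float = 2.0
    alpha: float = 0.05


@dataclass
class RunConfig:
    """Top-level configuration for an end-to-end run."""

    seed: int = 0
    vessels: VesselStageConfig = field(default_factory=VesselStageConfig)
    dce: DceStageConfig = field(default_factory=DceStageConfig)
    growth: GrowthStageConfig = field(default_factory=GrowthStageConfig)
    verbosity: int = 1

    def validate(self) -> "RunConfig":
        v, d, g = self.vessels, self.dce, self.growth
        checks = [
            (0 <= v.pericyte_fraction <= 1, "vessels.pericyte_fraction must be in [0,1]"),
            (v.pixel_pitch > 0, "vessels.pixel_pitch must be positive"),
            (v.n_vessels >= 0, "vessels.n_vessels must be non-negative"),
            (1 <= v.min_votes <= v.n_annotators,
             "vessels.min_votes must be in [1, n_annotators]"),
            (0 <= v.annotator_fp_rate <= 1 and 0 <= v.annotator_fn_rate <= 1,
             "annotator error rates must be in [0,1]"),
            (v.suppression_radius_px > 0 and v.adjacency_px > 0,
             "proximity radii must be positive"),
            (0 < d.core_fraction <= 1, "dce.core_fraction must be in (0,1]"),
            (d.iauc_window_s > 0, "dce.iauc_window_s must be positive"),
            (2 <= d.injection_frame < d.n_frames,
             "dce.injection_frame must be in [2, n_frames)"),
            (d.peak_concentration_mm >= 0, "dce.peak_concentration_mm must be >= 0"),
            (g.endpoint_volume > 0, "growth.endpoint_volume must be positive"),
            (g.growth_rate > 0, "growth.growth_rate must be positive"),
            (g.arrest_days >= 0, "growth.arrest_days must be non-negative"),
            (g.calliper_cv >= 0, "growth.calliper_cv must be non-negative"),
            (0 < g.alpha < 1, "growth.alpha must be in (0,1)"),
        ]
        for ok, message in checks:
            if not ok:
                raise ConfigError(message)
        return self

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        def build(dc_type, section):
            known = {f.name: f for f in fields(dc_type)}
            unknown = set(section) - set(known)
            if unknown:
                raise ConfigError(f"unknown {dc_type.__name__} keys: {sorted(unknown)}")
            coerced = {}
            for key, value in section.items():
                if isinstance(value, list):
                    value = tuple(value)
                coerced[key] = value
            return dc_type(**coerced)

        data = dict(data or {})
        cfg = cls(
            seed=int(data.pop("seed", 0)),
            vessels=build(VesselStageConfig, data.pop("vessels", {})),
            dce=build(DceStageConfig, data.pop("dce", {})),
            growth=build(GrowthStageConfig, data.pop("growth", {})),
            verbosity=int(data.pop("verbosity", 1)),
        )
        if data:
            raise ConfigError(f"unknown top-level keys: {sorted(data)}")
        return cfg.validate()

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def content_hash(self) -> str:
        """Stable hash identifying this configuration in provenance records."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
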