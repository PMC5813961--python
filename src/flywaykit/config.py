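"""Pipeline configuration with full defaulting to the published constants."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]

CONFIG_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Resolved configuration of a pipeline run.

    Thresholds default to the published field-method values; every run
    writes its resolved configuration beside its outputs so results are
    reproducible from config + seed alone.
    """

    sightings: str | None = None
    telemetry: str | None = None
    output_dir: str = "flywaykit_out"
    projection: str = (
        "+proj=eqdc +lat_1=20 +lat_2=60 +lat_0=40 +lon_0=-96 +x_0=0 +y_0=0 +ellps=GRS80 +datum=NAD83 +units=m"
    )
    window_height_km: float | str = 300.0  # or "auto"
    auto_height_candidates_km: list = field(default_factory=lambda: list(range(50, 701, 50)))
    core_levels: list = field(default_factory=lambda: [50, 75, 95])
    bootstrap: int = 1000
    mcmc_burn: int = 2000
    mcmc_keep: int = 10000
    median_min_sightings: int = 30
    overlap_years: list = field(default_factory=lambda: [2010, 2016])
    flight_velocity_ms: float = 2.6
    max_speed_kmh: float = 100.0
    min_turn_angle_deg: float = 5.0
    turn_leg_km: float = 50.0
    stopover_break_km: float = 15.0
    seed: int = 0
    schema_version: int = CONFIG_SCHEMA_VERSION

    def __post_init__(self) -> None:
        for name in ("flight_velocity_ms", "max_speed_kmh", "min_turn_angle_deg", "turn_leg_km", "stopover_break_km"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bootstrap < 2:
            raise ValueError("bootstrap must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        version = data.pop("schema_version", CONFIG_SCHEMA_VERSION)
        if version != CONFIG_SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {version}")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        overrides = {k: v for k, v in overrides.items() if v is not None}
        return replace(cfg, **overrides) if overrides else cfg

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path
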