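"""Run configuration: one YAML document (or dataclass) that fixes every
calibration value, threshold and seed of a pipeline run, hashed so output
tables are traceable to the exact configuration that produced them."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml


@dataclass
class RunConfig:
    pixel_size: float = 0.2  # μm/px
    frame_interval: float = 30.0  # s
    ap_axis_deg: float = 0.0
    band_width_um: float = 1.5
    min_detectability: float = 0.2
    min_prominence_fraction: float = 0.1
    max_displacement_um: float = 2.0
    cluster_preset: str = "follicle"
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if not 0.0 <= self.min_detectability <= 1.0:
            raise ValueError("min_detectability must lie in [0, 1]")
        if not 0.0 <= self.min_prominence_fraction <= 1.0:
            raise ValueError("min_prominence_fraction must lie in [0, 1]")
        if self.band_width_um < 0 or self.max_displacement_um <= 0:
            raise ValueError("band_width_um >= 0 and max_displacement_um > 0 required")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        """Short stable hash of the canonical configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
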