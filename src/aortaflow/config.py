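"""Resolved pipeline configuration with content hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

SCHEMA_VERSION = "1.0"


@dataclass
class PipelineConfig:
    """All tunables of the pipeline with their default cut-offs.

    Every run records the resolved config verbatim (plus its hash) in its
    output, so reports are reproducible byte-for-byte from config + seed.
    """

    # acquisition defaults
    venc: float = 180.0
    n_phases: int = 40
    pixel_spacing: float = 2.5
    grid_size: int = 64
    rr_interval: float = 1000.0
    # severity thresholds
    reference_rvol: float = 42.0  # mL, ascending
    reference_rf: float = 33.0  # %, ascending
    da_rvol: float = 17.0  # mL, descending
    da_rf: float = 23.0  # %, descending
    hfr_floor: float = 10.0  # mL/s
    dfr_velocity: float = 19.5  # cm/s
    diameter_dilated: float = 40.0  # mm
    offset_limit: float = 0.6  # cm/s
    # conventions
    rounding: str = "nearest"  # nearest | floor
    dfr_definition: str = "end_diastole"  # end_diastole | mean_diastole
    ci_method: str = "wilson"  # wilson | exact
    # randomness
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("reference_rvol", "reference_rf", "da_rvol", "da_rf",
                     "hfr_floor", "dfr_velocity", "diameter_dilated", "offset_limit"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Short SHA-256 of the canonical JSON encoding."""
        canonical = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
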