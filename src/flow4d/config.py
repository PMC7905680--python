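"""Run configuration and provenance manifest.

``StudyConfig`` is a single YAML/JSON document that round-trips
losslessly; unknown keys are rejected so typos fail loudly instead of
silently falling back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import List, Optional, Tuple

import yaml


@dataclass
class StudyConfig:
    """Pipeline configuration (defaults mirror the study conditions)."""

    # phantom grid
    grid_shape: Tuple[int, int, int] = (56, 56, 56)
    spacing_mm: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_frames: int = 20
    # fluid constants (CGS)
    rho: float = 1.06
    mu: float = 0.04
    # phantom dynamics / acquisition
    systolic_fraction: float = 0.35
    venc: float = 150.0
    snr: Optional[float] = None  # None: no velocity noise
    # cohort
    chamber: str = "LV"
    seed: int = 0
    # statistics
    alpha: float = 0.05
    posthoc_nonparametric: str = "mannwhitney"
    stats_enabled: bool = True
    stats_metrics: Tuple[str, ...] = ("vorticity_star", "ke_sys_star", "dissipation_star")

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.stats_metrics = tuple(self.stats_metrics)
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["spacing_mm"] = list(self.spacing_mm)
        d["stats_metrics"] = list(self.stats_metrics)
        return d

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record written next to every pipeline output."""

    tool_version: str
    config_hash: str
    seed: int
    stages: List[str] = field(default_factory=list)
    input_hashes: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def start(self) -> None:
        self.started = datetime.now(timezone.utc).isoformat()

    def finish(self) -> None:
        self.finished = datetime.now(timezone.utc).isoformat()

    def add_stage(self, name: str) -> None:
        self.stages.append(name)

    def write(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]
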