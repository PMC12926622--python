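"""Pipeline configuration: every analysis constant in one place.

Defaults reproduce the study's constants: 240 Hz sampling, 5-sample
position smoothing, 5 cm/s onset threshold held for 100 ms, 0.2 N offset
threshold, peak velocity within 67% of the movement, test-force calibration
band [1.85, 2.15] N, timing bins at 12.5/37.5/62.5/87.5%, McFadden R^2 gate
of 0.2, and alpha 0.05.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .design import SessionDesign
from .population import PopulationParams


@dataclass(frozen=True)
class Thresholds:
    onset_speed: float = 5.0  # cm/s
    onset_hold_ms: float = 100.0
    offset_force: float = 0.2  # N
    smoothing_window: int = 5  # samples
    peak_window_fraction: float = 0.67
    test_force_min: float = 1.85  # N
    test_force_max: float = 2.15  # N
    bin_edges: tuple[float, float, float, float] = (12.5, 37.5, 62.5, 87.5)
    r2_threshold: float = 0.2
    alpha: float = 0.05
    dip_speed: float = 1.0  # cm/s; continuity sub-rule of rejection rule (d)
    dip_max_ms: float = 150.0
    retreat_cm: float = 5.0


@dataclass
class PipelineConfig:
    n_participants: int = 28
    seed: int = 0
    sessions: tuple[str, ...] = ("vision", "no_vision")
    design: SessionDesign = field(default_factory=SessionDesign)
    population: PopulationParams = field(default_factory=PopulationParams)
    thresholds: Thresholds = field(default_factory=Thresholds)
    attenuation: bool = True  # False simulates null observers
    write_traces: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of every analysis-relevant parameter (seed included)."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "design" in kwargs:
            d = dict(kwargs["design"])
            if "comparison_intensities" in d:
                d["comparison_intensities"] = tuple(d["comparison_intensities"])
            for key in ("trial_groups", "fingers"):
                if key in d:
                    d[key] = tuple(d[key])
            kwargs["design"] = SessionDesign(**d)
        if "population" in kwargs:
            p = dict(kwargs["population"])
            if "jnd_bounds" in p:
                p["jnd_bounds"] = tuple(p["jnd_bounds"])
            kwargs["population"] = PopulationParams(**p)
        if "thresholds" in kwargs:
            t = dict(kwargs["thresholds"])
            if "bin_edges" in t:
                t["bin_edges"] = tuple(t["bin_edges"])
            kwargs["thresholds"] = Thresholds(**t)
        if "sessions" in kwargs:
            kwargs["sessions"] = tuple(kwargs["sessions"])
        return cls(**kwargs)
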