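"""Pipeline configuration: defaults, YAML/JSON loading, and hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .exposure import ForageParameters, NestParameters

DEFAULT_TRANSLOCATIONS = (0.10, 0.25, 0.50, 0.75, 1.00)
DEFAULT_SCENARIOS = ("chronic", "acute")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a pipeline run needs; every default is overridable.

    Paths may be None when a command supplies its own inputs (e.g. the
    packaged endpoint table, or synthetic residues generated on the fly).
    """

    residue_csv: str | None = None
    endpoint_csv: str | None = None
    nest: NestParameters = field(default_factory=NestParameters)
    forage: ForageParameters = field(default_factory=ForageParameters)
    scenarios: tuple[str, ...] = DEFAULT_SCENARIOS
    translocations: tuple[float, ...] = DEFAULT_TRANSLOCATIONS
    risk_threshold: float = 0.05
    bootstrap_iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0 < t <= 1 for t in self.translocations):
            raise ValueError("translocation fractions must be in (0, 1]")
        if not 0 < self.risk_threshold < 1:
            raise ValueError("risk_threshold must be in (0, 1)")
        if self.bootstrap_iterations < 1:
            raise ValueError("bootstrap_iterations must be >= 1")
        bad = [s for s in self.scenarios if s not in ("chronic", "acute")]
        if bad:
            raise ValueError(f"unknown scenarios: {bad}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["nest"] = asdict(self.nest)
        d["forage"] = asdict(self.forage)
        d["scenarios"] = list(self.scenarios)
        d["translocations"] = list(self.translocations)
        return d

    def config_hash(self) -> str:
        """Short stable hash stamped into every report for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        nest = NestParameters(**d.pop("nest", {}))
        forage = ForageParameters(**d.pop("forage", {}))
        if "scenarios" in d:
            d["scenarios"] = tuple(d["scenarios"])
        if "translocations" in d:
            d["translocations"] = tuple(d["translocations"])
        return cls(nest=nest, forage=forage, **d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load YAML (JSON is a YAML subset and is accepted too)."""
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)
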