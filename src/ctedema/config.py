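"""Pipeline configuration: one record serialized into every results bundle."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import DEFAULT_CONFOUNDERS
from .intracranial import IntracranialParams
from .mirroring import SymmetrySearch


@dataclass
class PipelineConfig:
    """Everything that parameterizes a run, for provenance."""

    hu_low: float = 20.0
    hu_high: float = 80.0
    filter_ipsilateral: bool = False
    intracranial: IntracranialParams = field(default_factory=IntracranialParams)
    symmetry: SymmetrySearch = field(default_factory=SymmetrySearch)
    per_ml: float = 10.0
    confounders: list[str] = field(default_factory=lambda: list(DEFAULT_CONFOUNDERS))
    output_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.hu_low < self.hu_high:
            raise ValueError(f"hu_low ({self.hu_low}) must be < hu_high "
                             f"({self.hu_high})")
        if self.per_ml <= 0:
            raise ValueError("per_ml must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("intracranial"), dict):
            d["intracranial"] = IntracranialParams(**d["intracranial"])
        if isinstance(d.get("symmetry"), dict):
            d["symmetry"] = SymmetrySearch(**d["symmetry"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = (json.loads(text) if path.suffix == ".json"
                else yaml.safe_load(text)) or {}
        return cls.from_dict(data)
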