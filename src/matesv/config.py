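"""Pipeline configuration: one YAML-loadable object covering every knob."""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

import yaml

from matesv.calling import CallerConfig


@dataclass
class PipelineConfig:
    """Settings for the simulate -> call -> annotate -> validate chain.

    ``cutoff`` may be 'auto' (twice the estimated median insert) or a fixed
    bp value.  Unknown keys in a config file are rejected outright.
    """

    orientation: str = "RF"
    read_length: int = 36
    min_support: int = 6
    cutoff: object = "auto"
    mapq_threshold: int = 20
    reciprocal_overlap: float = 0.5
    seed: int = 0
    pairs: Optional[str] = None
    genes: Optional[str] = None
    cytobands: Optional[str] = None
    centromeres: Optional[str] = None
    output_dir: str = "."

    def __post_init__(self):
        for name in ("read_length", "min_support", "mapq_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cutoff != "auto" and int(self.cutoff) <= 0:
            raise ValueError("cutoff must be 'auto' or a positive bp value")
        if not 0 < self.reciprocal_overlap <= 1:
            raise ValueError("reciprocal_overlap must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def caller_config(self) -> CallerConfig:
        override = None if self.cutoff == "auto" else int(self.cutoff) // 2
        return CallerConfig(orientation=self.orientation,
                            read_length=self.read_length,
                            mapq_threshold=self.mapq_threshold,
                            min_support=self.min_support,
                            median_override=override)
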