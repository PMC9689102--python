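"""Pipeline configuration with YAML round-tripping.

Defaults reproduce the published operating point: 160 x 160 model
input, polygon area threshold 0.25 % of the frame, focal loss with
γ = 2.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .enhance import EnhanceParams
from .polygons import PolygonConfig


@dataclass
class PipelineConfig:
    enhance: EnhanceParams = field(default_factory=EnhanceParams)
    polygons: PolygonConfig = field(default_factory=PolygonConfig)
    model_path: str | None = None
    gamma: float = 2.0
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "enhance" in d and isinstance(d["enhance"], dict):
            d["enhance"] = EnhanceParams(**d["enhance"])
        if "polygons" in d and isinstance(d["polygons"], dict):
            d["polygons"] = PolygonConfig(**d["polygons"])
        cfg = cls(**d)
        if cfg.gamma < 0:
            raise ValueError("gamma must be >= 0")
        return cfg

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
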