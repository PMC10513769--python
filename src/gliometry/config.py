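"""Run configuration: one YAML/JSON file plus flag overrides, fully serializable."""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import yaml

from .rano import RanoConfig


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serialized into every output dir."""

    label_map: dict[int, str] | None = None
    rano: RanoConfig = field(default_factory=RanoConfig)
    resample: bool = True
    resample_mm: float = 1.0
    axial_axis: int | None = None
    metrics: tuple[str, ...] = ("spd2d", "spd25d", "volume")
    thresholds: tuple[float, ...] = (0.25, 0.40)
    out_dir: str = "."
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        try:
            if "rano" in d and isinstance(d["rano"], dict):
                d["rano"] = RanoConfig(**d["rano"])
            if d.get("label_map") is not None:
                d["label_map"] = {int(k): str(v) for k, v in d["label_map"].items()}
            for tup in ("metrics", "thresholds"):
                if tup in d and d[tup] is not None:
                    d[tup] = tuple(d[tup])
            return cls(**d)
        except (TypeError, ValueError) as e:
            raise ConfigError(str(e)) from e

    @classmethod
    def load(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as f:
            if str(path).endswith(".json"):
                d = json.load(f)
            else:
                d = yaml.safe_load(f)
        if d is None:
            d = {}
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(d)

    def dump(self, path: str | os.PathLike) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)
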