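"""Run configuration: one YAML file fully determines a reproduction run."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .recording import ProtocolConfig
from .synthetic import GeneratorConfig


def _tupleize(obj):
    """YAML round-trips tuples as lists; restore tuples where needed."""
    if isinstance(obj, list):
        return tuple(obj)
    if isinstance(obj, dict):
        return {k: _tupleize(v) for k, v in obj.items()}
    return obj


@dataclass
class RunConfig:
    """Everything a full pipeline run depends on, serializable to YAML."""

    n_subjects: int = 7
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    montages: tuple[str, ...] = ("left3",)
    schemes: tuple[str, ...] = ("default",)
    classifier_params: dict = field(default_factory=dict)
    neg_ratio: float = 10.0
    split_by: str = "trial"
    attack_knowledge_level: float = 1.0
    attack_attempts: int = 200

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        gen = data.pop("generator", {})
        proto = data.pop("protocol", {})
        return cls(
            generator=GeneratorConfig(**{k: _tupleize(v) for k, v in gen.items()}),
            protocol=ProtocolConfig(**proto),
            **{k: _tupleize(v) if k in ("montages", "schemes") else v for k, v in data.items()},
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(data)
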