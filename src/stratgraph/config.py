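"""Run configuration: nested sections mirroring the library dataclasses,
YAML/JSON (de)serialization with defaults injected, unknown-key rejection
and dotted-path overrides."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class CohortSection:
    n_patients: int = 200
    n_steps: int = 12
    n_risk_classes: int = 4
    class_mix: list = field(default_factory=lambda: [0.183, 0.241, 0.312, 0.264])
    missing_rate: float = 0.124
    n_clusters: int = 8
    cluster_signal: float = 2.0
    category_tail_exponent: float = 1.2


@dataclass
class GraphSection:
    sigma: float = 2.0
    tau: float = 0.3
    weight_floor: float = 0.01


@dataclass
class EncoderSection:
    hidden_dim: int = 256
    graph_layers: int = 3
    attention_heads: int = 8
    temporal_window: int = 12
    dropout: float = 0.3


@dataclass
class TrainSection:
    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 20
    weight_decay: float = 1e-5
    graph_update_every: int = 1


@dataclass
class LossSection:
    lambda1: float = 1.0
    lambda2: float = 0.5
    lambda3: float = 1e-5


@dataclass
class EvaluationSection:
    fractions: list = field(default_factory=lambda: [0.70, 0.15, 0.15])
    n_boot: int = 1000
    mc_passes: int = 50


@dataclass
class DecodeSection:
    mode: str = "sample"
    max_len: int = 8
    incompat_rate: float = 0.25


@dataclass
class RunConfig:
    cohort: CohortSection = field(default_factory=CohortSection)
    graph: GraphSection = field(default_factory=GraphSection)
    encoder: EncoderSection = field(default_factory=EncoderSection)
    train: TrainSection = field(default_factory=TrainSection)
    loss: LossSection = field(default_factory=LossSection)
    evaluation: EvaluationSection = field(default_factory=EvaluationSection)
    decode: DecodeSection = field(default_factory=DecodeSection)
    output_dir: str = "runs/default"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


class ConfigError(ValueError):
    pass


def _build_section(cls, data: dict, path: str):
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"unknown key(s) under '{path}': {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        expected = f.type if isinstance(f.type, type) else None
        if f.name in ("class_mix", "fractions"):
            if not isinstance(value, (list, tuple)):
                raise ConfigError(f"'{path}.{name}' must be a list")
            value = [float(v) for v in value]
        elif isinstance(f.default, bool):
            if not isinstance(value, bool):
                raise ConfigError(f"'{path}.{name}' must be a boolean")
        elif isinstance(f.default, int) and not isinstance(f.default, bool):
            if isinstance(value, bool) or not isinstance(value, (int,)):
                raise ConfigError(f"'{path}.{name}' must be an integer")
        elif isinstance(f.default, float):
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise ConfigError(f"'{path}.{name}' must be a number")
            value = float(value)
        elif isinstance(f.default, str):
            if not isinstance(value, str):
                raise ConfigError(f"'{path}.{name}' must be a string")
        kwargs[name] = value
    return cls(**kwargs)


def config_from_dict(data: dict) -> RunConfig:
    data = dict(data or {})
    fields = {f.name: f for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for name, f in fields.items():
        if name not in data:
            continue
        value = data[name]
        if f.default_factory is not dataclasses.MISSING:
            if not isinstance(value, dict):
                raise ConfigError(f"section '{name}' must be a mapping")
            kwargs[name] = _build_section(f.default_factory, value, name)
        elif name == "seed":
            if isinstance(value, bool) or not isinstance(value, int):
                raise ConfigError("'seed' must be an integer")
            kwargs[name] = value
        elif name == "output_dir":
            if not isinstance(value, str):
                raise ConfigError("'output_dir' must be a string")
            kwargs[name] = value
    return RunConfig(**kwargs)


def load_config(path: str | Path | None = None,
                overrides: list[str] | None = None) -> RunConfig:
    """Load YAML/JSON config (missing/empty file -> all defaults), then
    apply dotted overrides like ``train.batch_size=16``."""
    data: dict = {}
    if path is not None:
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".json":  # YAML 1.1 floats reject JSON's 1e-05
            data = json.loads(text) if text.strip() else {}
        else:
            data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
    for ov in overrides or []:
        if "=" not in ov:
            raise ConfigError(f"override '{ov}' must look like a.b=value")
        key, raw = ov.split("=", 1)
        value = yaml.safe_load(raw)
        node = data
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
            if not isinstance(node, dict):
                raise ConfigError(f"override path '{key}' conflicts")
        node[parts[-1]] = value
    return config_from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".json":
        path.write_text(json.dumps(config.to_dict(), indent=2))
    else:
        path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
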