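"""Run configuration: one YAML file describing a full reproducible run.

The file round-trips losslessly through :func:`RunConfig.to_yaml` /
:func:`RunConfig.from_yaml`; unknown keys are rejected with a field-level
message.  Flat overrides use ``section.key=value`` syntax.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .mol_data import FixtureSpec
from .nets import NetworkConfig
from .sampling import SamplerConfig
from .sde import DiffusionSpec, NoiseSchedule
from .training import TrainConfig
from .vocab import AtomVocabulary

__all__ = ["RunConfig", "apply_overrides", "config_hash"]


def _from_dict(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in section '{path}'")
    return cls(**data)


def _schedule_dict(s: NoiseSchedule) -> dict:
    return {"kind": s.kind, "beta_min": s.beta_min, "beta_max": s.beta_max, "T": s.T}


@dataclass
class RunConfig:
    seed: int = 0
    vocabulary: AtomVocabulary = field(default_factory=AtomVocabulary)
    fixtures: FixtureSpec = field(default_factory=FixtureSpec)
    diffusion: DiffusionSpec = field(default_factory=DiffusionSpec)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    out_dir: str = "runs"

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "vocabulary": {
                "symbols": list(self.vocabulary.symbols),
                "valencies": dict(self.vocabulary.valencies),
            },
            "fixtures": {
                "templates": list(self.fixtures.templates),
                "count_per_template": self.fixtures.count_per_template,
                "jitter_std": self.fixtures.jitter_std,
                "seed": self.fixtures.seed,
            },
            "diffusion": {
                "schedule_x": _schedule_dict(self.diffusion.schedule_x),
                "schedule_p": _schedule_dict(self.diffusion.schedule_p),
                "schedule_a": _schedule_dict(self.diffusion.schedule_a),
            },
            "network": dataclasses.asdict(self.network),
            "train": dataclasses.asdict(self.train),
            "sampler": dataclasses.asdict(self.sampler),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = {
            "seed", "out_dir", "vocabulary", "fixtures", "diffusion",
            "network", "train", "sampler",
        }
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown top-level key(s) {sorted(unknown)}")
        vocab_d = data.get("vocabulary", {})
        vocabulary = AtomVocabulary(
            symbols=tuple(vocab_d.get("symbols", AtomVocabulary().symbols)),
            valencies=dict(vocab_d.get("valencies", AtomVocabulary().valencies)),
        )
        fixtures_d = dict(data.get("fixtures", {}))
        if "templates" in fixtures_d:
            fixtures_d["templates"] = tuple(fixtures_d["templates"])
        fixtures = _from_dict(FixtureSpec, fixtures_d, "fixtures")
        diff_d = data.get("diffusion", {})
        diffusion = DiffusionSpec(
            **{
                name: _from_dict(NoiseSchedule, diff_d.get(name, {}), f"diffusion.{name}")
                for name in ("schedule_x", "schedule_p", "schedule_a")
            }
        )
        return cls(
            seed=int(data.get("seed", 0)),
            out_dir=str(data.get("out_dir", "runs")),
            vocabulary=vocabulary,
            fixtures=fixtures,
            diffusion=diffusion,
            network=_from_dict(NetworkConfig, data.get("network", {}), "network"),
            train=_from_dict(TrainConfig, data.get("train", {}), "train"),
            sampler=_from_dict(SamplerConfig, data.get("sampler", {}), "sampler"),
        )

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)


def _parse_scalar(value: str):
    try:
        return yaml.safe_load(value)
    except yaml.YAMLError:
        return value


def apply_overrides(config: RunConfig, overrides: list[str]) -> RunConfig:
    """Apply flat ``section.key=value`` overrides to a config."""
    data = config.to_dict()
    for item in overrides:
        if "=" not in item:
            raise ValueError(f"override {item!r} is not of the form section.key=value")
        dotted, value = item.split("=", 1)
        keys = dotted.split(".")
        node = data
        for key in keys[:-1]:
            if key not in node or not isinstance(node[key], dict):
                raise ValueError(f"unknown override section {dotted!r}")
            node = node[key]
        if keys[-1] not in node:
            raise ValueError(f"unknown override key {dotted!r}")
        node[keys[-1]] = _parse_scalar(value)
    return RunConfig.from_dict(data)


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]
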