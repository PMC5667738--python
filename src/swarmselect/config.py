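"""YAML run configuration for the command-line pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .gbpso import SwarmConfig
from .wrapper import FitnessConfig, PipelineConfig

__all__ = ["RunConfig", "load_run_config"]


class ConfigError(ValueError):
    """Configuration schema violation, reported with its field path."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run from disk."""

    input: str
    output_dir: str
    label_column: str = "class"
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _build(cls, data: dict, path: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown field(s) {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from None


def load_run_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Schema errors are raised as :class:`ConfigError` with the offending
    field path.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    for key in ("input", "output_dir"):
        if key not in raw:
            raise ConfigError(f"{key}: required field missing")
    pipe_raw = dict(raw.get("pipeline", {}))
    swarm = _build(SwarmConfig, dict(pipe_raw.pop("swarm", {})), "pipeline.swarm")
    fitness = _build(FitnessConfig, dict(pipe_raw.pop("fitness", {})), "pipeline.fitness")
    if "filters" in pipe_raw:
        pipe_raw["filters"] = tuple(pipe_raw["filters"])
    pipeline = _build(
        PipelineConfig, {**pipe_raw, "swarm": swarm, "fitness": fitness}, "pipeline"
    )
    return RunConfig(
        input=str(raw["input"]),
        output_dir=str(raw["output_dir"]),
        label_column=str(raw.get("label_column", "class")),
        pipeline=pipeline,
    )
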