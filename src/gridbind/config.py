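"""YAML run configuration and provenance records for the CLI."""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import asdict, fields
from pathlib import Path

import yaml

from .errors import GridbindError
from .models import ModelConfig
from .training import TrainingConfig

try:
    from . import __version__
except ImportError:  # pragma: no cover
    __version__ = "unknown"


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise GridbindError(f"{path}: expected a YAML mapping at the top level")
    return data


def _build(cls, section: dict, where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise GridbindError(f"{where}: unknown keys {sorted(unknown)}; allowed: {sorted(allowed)}")
    for key in ("conv_channels", "conv_strides", "head_widths"):
        if key in section and isinstance(section[key], list):
            section[key] = tuple(section[key])
    return cls(**section)


def load_run_config(path) -> tuple[ModelConfig, TrainingConfig]:
    """A train-run YAML has two sections: ``model`` and ``training``."""
    data = load_yaml(path)
    model = _build(ModelConfig, dict(data.get("model", {})), f"{path}:model")
    training = _build(TrainingConfig, dict(data.get("training", {})), f"{path}:training")
    return model, training


def config_hash(obj) -> str:
    if hasattr(obj, "__dataclass_fields__"):
        obj = asdict(obj)
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def append_run_record(out_dir, command: str, config, seeds, inputs, outputs) -> None:
    """Append exactly one provenance record per CLI run (JSONL)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "command": command,
        "config_hash": config_hash(config) if config is not None else None,
        "seeds": seeds,
        "inputs": [str(p) for p in inputs],
        "outputs": [str(p) for p in outputs],
        "tool_version": __version__,
        "argv": sys.argv,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    with open(out_dir / "run_manifest.jsonl", "a") as fh:
        fh.write(json.dumps(record) + "\n")
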