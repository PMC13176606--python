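"""Configuration loading and run manifests.

A run configuration is a JSON or YAML file with up to four blocks —
``preprocess``, ``training``, ``cv`` and ``simulate`` — whose values
override built-in defaults; command-line flags override the file in turn.
Unknown keys are rejected so typos fail loudly. Every completed CLI run
writes a manifest (resolved config, seeds, input digests, version) next to
its outputs so it can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import yaml

from .data import ValidationError
from .objectives import LossWeights
from .preprocess import PreprocessConfig
from .simulate import SimConfig
from .training import TrainingConfig

CV_DEFAULTS = {"n_folds": 5, "reuse_sc_autoencoder": True}


def default_config() -> dict:
    return {
        "preprocess": dataclasses.asdict(PreprocessConfig()),
        "training": dataclasses.asdict(TrainingConfig()),
        "cv": dict(CV_DEFAULTS),
        "simulate": dataclasses.asdict(SimConfig()),
    }


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge defaults <- config file <- overrides, rejecting unknown keys."""
    merged = default_config()
    for source, label in ((_read_file(path), str(path)), (overrides or {}, "overrides")):
        for block, values in source.items():
            if block not in merged:
                raise ValidationError(
                    f"unknown config block {block!r} in {label}; valid: {sorted(merged)}"
                )
            if values is None:
                continue
            for key, value in values.items():
                if key not in merged[block]:
                    raise ValidationError(
                        f"unknown key {block}.{key} in {label}; "
                        f"valid: {sorted(merged[block])}"
                    )
                if key == "weights" and isinstance(value, dict):
                    merged[block][key] = {**merged[block][key], **value}
                else:
                    merged[block][key] = value
    return merged


def _read_file(path) -> dict:
    if path is None:
        return {}
    text = Path(path).read_text()
    if not text.strip():
        return {}
    if str(path).endswith((".yaml", ".yml")):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValidationError("config file must contain a mapping of blocks")
    return data


def make_training_config(block: dict) -> TrainingConfig:
    block = dict(block)
    weights = block.pop("weights", {})
    return TrainingConfig(**block, weights=LossWeights(**weights)
                          if isinstance(weights, dict) else weights)


def make_preprocess_config(block: dict) -> PreprocessConfig:
    return PreprocessConfig(**block)


def make_sim_config(block: dict) -> SimConfig:
    return SimConfig(**block)


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: dict, inputs: dict | None = None, seed: int | None = None) -> Path:
    """Record everything needed to reproduce a run next to its outputs."""
    from . import __version__

    manifest = {
        "tool": "stimpute",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": config,
        "inputs": {name: {"path": str(p), "sha256": file_digest(p)}
                   for name, p in (inputs or {}).items()},
    }
    out = Path(out_dir) / "run_manifest.json"
    out.write_text(json.dumps(manifest, indent=1, default=str))
    return out


def verify_manifest(path) -> bool:
    """Recompute the input digests recorded in a manifest; True when all match."""
    manifest = json.loads(Path(path).read_text())
    return all(
        file_digest(entry["path"]) == entry["sha256"]
        for entry in manifest.get("inputs", {}).values()
    )
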