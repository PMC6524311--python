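"""YAML run configuration: packaged defaults plus user overrides."""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigurationError


def load_default_config() -> dict:
    """The packaged calibrated defaults (deep copy, safe to mutate)."""
    ref = resources.files("iplboost").joinpath("data/default_config.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge defaults ← YAML file ← explicit overrides (in that order).

    Unknown top-level or motion keys are rejected rather than silently
    ignored, so typos in config files surface as configuration errors.
    """
    cfg = load_default_config()
    layers = []
    if path is not None:
        try:
            with open(path, "r", encoding="utf-8") as fh:
                layers.append(yaml.safe_load(fh) or {})
        except OSError as exc:
            raise ConfigurationError(f"cannot read config file {path}: {exc}") from exc
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"invalid YAML in {path}: {exc}") from exc
    if overrides:
        layers.append(copy.deepcopy(overrides))
    for layer in layers:
        if not isinstance(layer, dict):
            raise ConfigurationError("config file must contain a mapping")
        for key, value in layer.items():
            if key == "motion":
                if not isinstance(value, dict):
                    raise ConfigurationError("'motion' must be a mapping")
                unknown = set(value) - set(cfg["motion"])
                if unknown:
                    raise ConfigurationError(f"unknown motion keys: {sorted(unknown)}")
                cfg["motion"].update(value)
            elif key in cfg:
                cfg[key] = value
            else:
                raise ConfigurationError(f"unknown config key: {key!r}")
    return cfg
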