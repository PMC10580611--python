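"""YAML round-trip for the full parameter tree.

The file mirrors the parameter table's section structure
(``population:``, ``prescribing:``, ``treatment:``, ``diversion:``,
``overdose:``, ``dynamics:``); any subset of keys may be given and the
rest keep their defaults.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .params import (ConfigError, DiversionParams, InternalDynamicsParams,
                     ModelParams, OverdoseHazardParams, PopulationParams,
                     PrescribingParams, TreatmentParams)

_SECTIONS = {
    "population": PopulationParams,
    "dynamics": InternalDynamicsParams,
    "prescribing": PrescribingParams,
    "treatment": TreatmentParams,
    "diversion": DiversionParams,
    "overdose": OverdoseHazardParams,
}


def params_to_dict(params: ModelParams) -> dict:
    out = {}
    for section in _SECTIONS:
        d = dataclasses.asdict(getattr(params, section))
        out[section] = {k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in d.items()}
    return out


def params_from_dict(data: dict) -> ModelParams:
    kwargs = {}
    for section, cls in _SECTIONS.items():
        entries = data.get(section, {}) or {}
        names = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(entries) - set(names)
        if unknown:
            raise ConfigError(f"unknown keys in '{section}': {sorted(unknown)}")
        coerced = {}
        for key, value in entries.items():
            if isinstance(value, list):
                value = tuple(value)
            coerced[key] = value
        kwargs[section] = cls(**coerced)
    params = ModelParams(**kwargs)
    params.validate()
    return params


def save_params(params: ModelParams, path) -> None:
    Path(path).write_text(yaml.safe_dump(params_to_dict(params),
                                         sort_keys=False))


def load_params(path) -> ModelParams:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must be a YAML mapping")
    return params_from_dict(data)
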