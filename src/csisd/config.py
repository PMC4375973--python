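"""YAML (de)serialisation for model, sampler and generator specifications.

The on-disk schema is a flat mapping per section::

    model:
      family: gaussian_conjugate
      alpha: 0.001
      beta: 0.001
      kBT: 1.0
      weights_mode: sampled
    sampler:
      n_steps: 1000000
      seed: 1
      sigma_mu: 0.1
      burn_in_fraction: 0.9
      report_stride: 10
    generator:
      n_residues: 500
      seed: 1
      family: gaussian

Unknown keys are an error, so typos fail loudly.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Dict, Union

import yaml

from .error_models import ModelSpec
from .sampler import SamplerConfig
from .synthetic import GeneratorSpec

_SECTIONS = {
    "model": ModelSpec,
    "sampler": SamplerConfig,
    "generator": GeneratorSpec,
}


def _from_dict(cls, data: Dict[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(data)
    # YAML maps tuples to lists; restore where the dataclass expects a tuple
    if cls is GeneratorSpec and "classes" in kwargs:
        kwargs["classes"] = tuple(kwargs["classes"])
    return cls(**kwargs)


def _to_dict(obj) -> Dict[str, Any]:
    d = dataclasses.asdict(obj)
    if isinstance(obj, GeneratorSpec):
        d["classes"] = list(d["classes"])
    return d


def model_spec_from_dict(data: Dict[str, Any]) -> ModelSpec:
    return _from_dict(ModelSpec, data)


def sampler_config_from_dict(data: Dict[str, Any]) -> SamplerConfig:
    return _from_dict(SamplerConfig, data)


def generator_spec_from_dict(data: Dict[str, Any]) -> GeneratorSpec:
    return _from_dict(GeneratorSpec, data)


def load_config(path: Union[str, Path]) -> Dict[str, Any]:
    """Load a YAML config file and build any recognised sections.

    Returns a dict with the parsed objects under ``model``, ``sampler`` and
    ``generator`` keys (only those present in the file).
    """
    with Path(path).open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"{path}: unknown sections {sorted(unknown)}")
    return {name: _from_dict(cls, raw[name]) for name, cls in _SECTIONS.items() if name in raw}


def save_config(path: Union[str, Path], **sections) -> None:
    """Write ``model=``/``sampler=``/``generator=`` objects to a YAML file."""
    unknown = set(sections) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown sections {sorted(unknown)}")
    payload = {name: _to_dict(obj) for name, obj in sections.items() if obj is not None}
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
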