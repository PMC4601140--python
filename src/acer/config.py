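"""Configuration file handling (coil model + sampler settings).

The configuration is a YAML key-value file with two optional sections::

    coil:
      coil_type: rigid          # rigid | inflatable
      surface: bottom-edge      # anchor name, or 1-2 [row, col] points
      A: 5.0                    # SNR gain at the coil surface (>= 1)
      tau_mm: 20.0              # exponential decay length
      d_cut_mm: 60.0            # depth of the final abrupt drop
      floor_gain: 1.0           # residual gain beyond the cutoff
    sampler:
      patch_radius: 1
      search_radius: 10
      n_accept: 64
      max_draws: 512
      seed: 0

An empty file yields all defaults.  Unknown keys are rejected
(fail-fast) with every offending key enumerated.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .coil import CoilModel
from .errors import ConfigurationError
from .reconstruct import SamplerConfig

__all__ = ["Config", "load_config", "dump_config"]

_COIL_KEYS = {"coil_type", "surface", "A", "tau_mm", "d_cut_mm", "floor_gain"}
_SAMPLER_KEYS = {"patch_radius", "search_radius", "n_accept", "max_draws", "seed"}


@dataclass(frozen=True)
class Config:
    coil: CoilModel
    sampler: SamplerConfig


def load_config(path) -> Config:
    """Load and validate a configuration file; see the module docstring."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError("configuration root must be a mapping")

    offending = [k for k in raw if k not in ("coil", "sampler")]
    coil_raw = raw.get("coil") or {}
    sampler_raw = raw.get("sampler") or {}
    if not isinstance(coil_raw, dict) or not isinstance(sampler_raw, dict):
        raise ConfigurationError("'coil' and 'sampler' sections must be mappings")
    offending += [f"coil.{k}" for k in coil_raw if k not in _COIL_KEYS]
    offending += [f"sampler.{k}" for k in sampler_raw if k not in _SAMPLER_KEYS]
    if offending:
        raise ConfigurationError(f"unknown configuration keys: {sorted(offending)}")

    coil_kwargs = {}
    if "coil_type" in coil_raw:
        coil_kwargs["coil_type"] = coil_raw["coil_type"]
    if "surface" in coil_raw:
        coil_kwargs["surface"] = coil_raw["surface"]
    if "A" in coil_raw:
        coil_kwargs["surface_gain"] = float(coil_raw["A"])
    if "tau_mm" in coil_raw:
        coil_kwargs["decay_length_mm"] = float(coil_raw["tau_mm"])
    if "d_cut_mm" in coil_raw:
        coil_kwargs["cutoff_mm"] = float(coil_raw["d_cut_mm"])
    if "floor_gain" in coil_raw:
        coil_kwargs["floor_gain"] = float(coil_raw["floor_gain"])
    coil = CoilModel(**coil_kwargs)
    sampler = SamplerConfig(**{k: int(v) for k, v in sampler_raw.items()})
    return Config(coil=coil, sampler=sampler)


def dump_config(path, *, coil: CoilModel, sampler: SamplerConfig) -> None:
    """Write a configuration file that :func:`load_config` restores exactly."""
    surface = coil.surface if isinstance(coil.surface, str) else [list(p) for p in coil.surface]
    doc = {
        "coil": {
            "coil_type": coil.coil_type,
            "surface": surface,
            "A": float(coil.surface_gain),
            "tau_mm": float(coil.decay_length_mm),
            "d_cut_mm": float(coil.cutoff_mm),
            "floor_gain": float(coil.floor_gain),
        },
        "sampler": {
            "patch_radius": sampler.patch_radius,
            "search_radius": sampler.search_radius,
            "n_accept": sampler.n_accept,
            "max_draws": sampler.max_draws,
            "seed": sampler.seed,
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
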