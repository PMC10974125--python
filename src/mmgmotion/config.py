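"""Nested run configuration with defaults, validation and YAML/JSON loading.

The configuration tree mirrors the pipeline stages.  Unknown keys are rejected
with their dotted path; values must match the type of the corresponding
default (ints are accepted where floats are expected).  Resolution is
idempotent: resolving an already-resolved configuration is a no-op.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised for unknown keys, type mismatches or unreadable config files."""


#: full default configuration; every run option lives here.
DEFAULTS: dict = {
    "synthetic": {
        "exercise": "bicep_curl",
        "duration_s": 60.0,
        "rate_hz": 1000.0,
        "motion_freq_hz": [0.3, 0.7],
        "mmg_band_hz": [10.0, 50.0],
        "semg_band_hz": [20.0, 450.0],
        "pseudo_accel_cutoff_hz": 5.0,
        "snr_db": 15.0,
        "activation_delay_ms": 50.0,
        "n_sensors": 4,
        "n_trials": 5,
        "seed": 0,
    },
    "vmd": {
        "alpha": 2000.0,
        "tau": 0.0,
        "tol": 1e-7,
        "max_iter": 500,
        "init": "uniform",
        "dc_mode": False,
    },
    "de": {
        "pop_size": 15,
        "F": 0.5,
        "CR": 0.9,
        "generations": 30,
        "K_min": 2,
        "K_max": 8,
        "alpha_min": 100.0,
        "alpha_max": 10000.0,
        "seed": 0,
        "aggregation": "mean",
        "fitness_segment_s": 4.0,
        "fitness_max_iter": 200,
    },
    "preprocess": {
        "band_low_hz": 10.0,
        "band_high_hz": 450.0,
        "filter_order": 4,
        "envelope_cutoff_hz": 5.0,
        "normalization": "minmax_01",
    },
    "windowing": {
        "window_ms": 1000.0,
        "step_ms": 200.0,
        "seq_len": 20,
        "out_len": 20,
        "latency_budget_ms": 300.0,
    },
    "split": {
        "test_fraction": 0.2,
        "scheme": "by_block",
        "seed": 0,
    },
    "model": {
        "kind": "transformer",
        "n_features": 8,
        "n_heads": 2,
        "n_layers": 1,
        "d_ff": 64,
        "dropout": 0.1,
        "lr": 1e-3,
        "batch_size": 64,
        "epochs": 30,
        "seed": 0,
    },
}


def _merge(defaults: dict, override: dict, path: str) -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        dotted = f"{path}.{key}" if path else str(key)
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {dotted}")
        default = defaults[key]
        if isinstance(default, dict):
            if not isinstance(value, dict):
                raise ConfigError(f"{dotted}: expected a mapping")
            out[key] = _merge(default, value, dotted)
        else:
            out[key] = _check_type(dotted, value, default)
    return out


def _check_type(dotted: str, value, default):
    if isinstance(default, bool):
        if not isinstance(value, bool):
            raise ConfigError(f"{dotted}: expected bool, got {type(value).__name__}")
        return value
    if isinstance(default, int) and not isinstance(default, bool):
        if isinstance(value, bool) or not isinstance(value, int):
            raise ConfigError(f"{dotted}: expected int, got {type(value).__name__}")
        return value
    if isinstance(default, float):
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"{dotted}: expected number, got {type(value).__name__}")
        return float(value)
    if isinstance(default, str):
        if not isinstance(value, str):
            raise ConfigError(f"{dotted}: expected string, got {type(value).__name__}")
        return value
    if isinstance(default, list):
        if not isinstance(value, (list, tuple)):
            raise ConfigError(f"{dotted}: expected list, got {type(value).__name__}")
        return [float(v) for v in value]
    raise ConfigError(f"{dotted}: unsupported configuration type")


def resolve_config(override: dict | None = None) -> dict:
    """Merge ``override`` onto :data:`DEFAULTS`, validating keys and types."""
    return _merge(DEFAULTS, override or {}, "")


def load_config(path: str | Path | None) -> dict:
    """Load a YAML/JSON mapping from ``path`` and resolve it onto the defaults.

    ``None`` yields the pure default configuration.
    """
    if path is None:
        return resolve_config({})
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return resolve_config(data)
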