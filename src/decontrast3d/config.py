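"""YAML run-configuration schema, validation and seed fan-out."""

from __future__ import annotations

import copy
import hashlib
import json
import os

import yaml

DEFAULTS = {
    "seed": 0,
    "log_level": "INFO",
    "window": [-1024.0, 1976.0],
    "simulate": {
        "n_cases": 20,
        "volume_shape": [64, 64, 32],
        "spacing_mm": [4.0, 4.0, 4.0],
        "noise_sd": 3.0,
        "deform_amplitude_mm": 0.0,
    },
    "preprocess": {
        "target_shape": None,
        "patch_size": [32, 32, 16],
        "patches_per_case": 4,
        "n_train": 16,
        "split_seed": 0,
    },
    "generator": {
        "n_levels": 4,
        "base_channels": 64,
        "max_channels": 512,
        "n_bottleneck_residual_blocks": 1,
    },
    "discriminator": {
        "n_layers": 3,
        "base_channels": 64,
        "max_channels": 256,
        "kernel_size": 4,
        "conditional": True,
    },
    "loss": {"lambda_l1": 10.0, "delta_perc": 10.0, "extractor_seed": 0},
    "train": {
        "total_epochs": 200,
        "const_lr_epochs": 100,
        "initial_lr": 2.0e-4,
        "checkpoint_every": 0,
    },
    "evaluate": {"overlap": 0.5, "target_wepl": 50.0},
}


class ConfigSchemaError(ValueError):
    pass


def _merge(defaults, user, path=""):
    out = copy.deepcopy(defaults)
    for key, val in (user or {}).items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigSchemaError(f"unknown configuration key: '{where}'")
        if isinstance(defaults[key], dict):
            if val is None:
                continue
            if not isinstance(val, dict):
                raise ConfigSchemaError(f"'{where}' must be a mapping")
            out[key] = _merge(defaults[key], val, where)
        else:
            out[key] = val
    return out


def validate_config(source) -> dict:
    """Load, schema-check and default-fill a run configuration.

    ``source`` is a YAML file path or an already-parsed mapping.  Unknown
    keys are rejected by name; validation is idempotent.  Cross-field
    checks: the patch size must be divisible by ``2**n_levels``.
    """
    if isinstance(source, dict):
        raw = source
    else:
        path = os.fspath(source)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigSchemaError(f"configuration root in {path} must be a mapping")
    cfg = _merge(DEFAULTS, raw)
    lo, hi = cfg["window"]
    if not lo < hi:
        raise ConfigSchemaError(f"window {cfg['window']} is degenerate (low >= high)")
    d = 2 ** int(cfg["generator"]["n_levels"])
    patch = cfg["preprocess"]["patch_size"]
    if any(int(p) % d != 0 for p in patch):
        raise ConfigSchemaError(
            f"patch_size {patch} is not divisible by 2**n_levels = {d}"
        )
    d2 = 2 ** int(cfg["discriminator"]["n_layers"])
    if any(int(p) % d2 != 0 for p in patch):
        raise ConfigSchemaError(
            f"patch_size {patch} is not divisible by 2**n_layers = {d2}"
        )
    return cfg


def config_digest(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def derive_seed(global_seed: int, module: str) -> int:
    """Stable per-module seed derived from the global seed.

    Hash-based fan-out keeps every pipeline stage independently
    reproducible from the single recorded seed.
    """
    digest = hashlib.sha256(f"{int(global_seed)}:{module}".encode()).hexdigest()
    return int(digest, 16) % (2**31)
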