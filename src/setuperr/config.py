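"""YAML configuration for the analysis pipeline.

One file with blocks ``io``, ``geometry``, ``sampler``, ``stats`` and
``generator``; any subset may be present and command-line flags override
file values.  :func:`load_config` merges user values over the defaults.
"""

from __future__ import annotations

from copy import deepcopy
from pathlib import Path
from typing import Any, Mapping

import yaml

from .rigid import RotationConvention
from .synthetic import GeneratorConfig

DEFAULTS: dict[str, dict[str, Any]] = {
    "io": {
        "delimiter": ",",
        "fractions_per_week": 5,
        "units": {"translation": "mm", "rotation": "deg"},
    },
    "geometry": {
        "axis_of": {"yaw": "z", "roll": "y", "pitch": "x"},
        "order": ["pitch", "roll", "yaw"],
        "intrinsic": True,
    },
    "sampler": {
        "r_grid": [0.0, 25.0, 50.0, 75.0, 100.0],
        "percentile": 95.0,
        "n_sim": 2000,
        "n_boot": 500,
        "ci_method": "percentile",
        "mode": "first_order",
        "n_rep_draws": 1000,
    },
    "stats": {
        "alpha": 0.05,
        "wilcoxon_exact_cutoff": 25,
        "wilcoxon_continuity_correction": True,
        "tau": 0.95,
        "contrast_n_boot": 200,
    },
    "generator": {},  # GeneratorConfig field overrides
}


def _merge(base: dict, override: Mapping) -> dict:
    out = deepcopy(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = deepcopy(v)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config file merged over the package defaults."""
    cfg = deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, Mapping):
            raise ValueError(f"config file {path} must hold a mapping")
        unknown = set(user) - set(DEFAULTS)
        if unknown:
            raise ValueError(
                f"unknown config block(s): {', '.join(sorted(unknown))}"
            )
        cfg = _merge(cfg, user)
    return cfg


def convention_from_config(cfg: Mapping) -> RotationConvention:
    """Build the machine rotation convention from the ``geometry`` block."""
    geo = cfg.get("geometry", DEFAULTS["geometry"])
    return RotationConvention(
        axis_of=dict(geo["axis_of"]),
        order=tuple(geo["order"]),
        intrinsic=bool(geo["intrinsic"]),
    )


def generator_config_from(cfg: Mapping, seed: int | None = None) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` from the ``generator`` block."""
    block = dict(cfg.get("generator", {}))
    for key in ("systematic_sd", "random_sd", "postcorrection_sd",
                "intrafraction_sd", "measurement_noise_sd"):
        if key in block:
            block[key] = tuple(block[key])
    if seed is not None:
        block["seed"] = seed
    return GeneratorConfig(**block).validate()
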