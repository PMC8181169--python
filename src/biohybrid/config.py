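"""YAML run-configuration loading, validation and manifest round-tripping.

A run configuration names a preset and optionally overrides replicate count,
seed and model parameters:

.. code-block:: yaml

    preset: b1_homog
    replicates: 14
    seed: 7
    params:
      sigma_bees: 0.3

Unknown top-level keys and unknown parameter names are rejected with an
error naming the offending key, so typos cannot silently fall back to
defaults.  ``materialize`` returns the fully defaulted configuration, which
round-trips unchanged through save/load.
"""

from __future__ import annotations

from dataclasses import asdict, fields, replace
from pathlib import Path

import yaml

from .bees import BeeParams
from .fish import FishParams
from .plants import PlantParams
from .presets import get_preset

__all__ = ["load_config", "save_config", "materialize", "params_class_for"]

_TOP_KEYS = {"preset", "replicates", "seed", "params"}

_PARAMS_BY_ORGANISM = {
    "bees": BeeParams,
    "fish": FishParams,
    "plants": PlantParams,
}


def params_class_for(organism: str):
    return _PARAMS_BY_ORGANISM[organism]


def _validate(cfg: dict) -> dict:
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a mapping")
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ValueError(
            f"unknown configuration key(s) {sorted(unknown)}; "
            f"allowed: {sorted(_TOP_KEYS)}"
        )
    if "preset" not in cfg:
        raise ValueError("configuration must name a 'preset'")
    preset = get_preset(str(cfg["preset"]))
    replicates = int(cfg.get("replicates", preset.n_replicates))
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    seed = int(cfg.get("seed", 0))
    params = dict(cfg.get("params") or {})
    cls = params_class_for(preset.organism)
    known = {f.name for f in fields(cls)}
    bad = set(params) - known
    if bad:
        raise ValueError(
            f"unknown parameter(s) {sorted(bad)} for {preset.organism} model; "
            f"known: {sorted(known)}"
        )
    # constructing and validating catches range violations (e.g. sigma > 1)
    full = replace(cls(), **params)
    validate = getattr(full, "validate", None)
    if validate is not None:
        validate()
    return {
        "preset": preset.name,
        "replicates": replicates,
        "seed": seed,
        "params": params,
    }


def load_config(path: str | Path) -> dict:
    """Load and validate a YAML run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return _validate(raw if raw is not None else {})


def materialize(cfg: dict) -> dict:
    """Fully defaulted configuration: every model parameter made explicit."""
    cfg = _validate(cfg)
    preset = get_preset(cfg["preset"])
    cls = params_class_for(preset.organism)
    full_params = asdict(replace(cls(), **cfg["params"]))
    return {**cfg, "params": full_params}


def save_config(cfg: dict, path: str | Path) -> None:
    cfg = _validate(cfg)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
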