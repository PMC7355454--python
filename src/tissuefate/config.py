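"""YAML run configuration with per-module sections and defaults."""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .phantom import PhantomConfig

DEFAULTS: dict = {
    "phantom": {},              # PhantomConfig field overrides
    "cohort": {"n_cases": 10, "sr_fraction": 0.5},
    "perfusion": {"n_baseline": 8, "severe_threshold_s": 8.0},
    "model": {"hyperparameters": None, "cv_folds": 5},
    "clinical": {"tertile_cutoffs": None},
}


def load_config(path: str | Path | None) -> dict:
    """Merge a YAML config file (may be absent) over the defaults."""
    cfg = {k: dict(v) for k, v in DEFAULTS.items()}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        for section, values in loaded.items():
            if section not in cfg:
                raise ValueError(f"unknown config section {section!r}")
            if values:
                cfg[section].update(values)
    return cfg


def phantom_config(cfg: dict, seed: int | None = None) -> PhantomConfig:
    """Build a PhantomConfig from the config's phantom section."""
    opts = dict(cfg.get("phantom", {}))
    if "shape" in opts:
        opts["shape"] = tuple(opts["shape"])
    for tup in ("core_adc", "penumbra_adc", "normal_adc"):
        if tup in opts:
            opts[tup] = tuple(opts[tup])
    if seed is not None:
        opts["seed"] = seed
    valid = {f.name for f in fields(PhantomConfig)}
    unknown = set(opts) - valid
    if unknown:
        raise ValueError(f"unknown phantom options: {sorted(unknown)}")
    return PhantomConfig(**opts)
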