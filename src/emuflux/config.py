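"""YAML configuration with one master seed.

A single document configures the whole pipeline; every stage derives
its own seed from the master seed through a fixed spawn schedule
(:func:`stage_seeds`), so one knob reproduces an entire run.
"""

from __future__ import annotations

import copy
from pathlib import Path

import numpy as np
import yaml

__all__ = ["default_config", "load_config", "stage_seeds", "STAGES"]

STAGES = ("sample", "simulate", "train", "fit", "ci", "evaluate")

_DEFAULTS: dict = {
    "seed": 1234,
    "scenario": "toy",  # toy | rich, or a model: {sbml, atom_map, bounds} block
    "model": None,
    "sampling": {
        "n_samples": 400,
        "method": "hit_and_run",
        "distribution": "log_uniform",
    },
    "simulation": {
        "timepoints": [0.25, 0.5, 1.0, 2.0],
        "rtol": 1.0e-8,
        "atol": 1.0e-10,
    },
    "measurements": {"noise_sd": 0.01},
    "surrogate": {
        "hidden_sizes": [216, 36, 6],
        "activation": "relu",
        "epochs": 40,
        "batch_size": 32,
        "learning_rate": 1.0e-3,
        "validation_fraction": 0.2,
        "log_concentrations": True,
    },
    "estimation": {"n_starts": 3, "concentrations": "estimate"},
    "ci": {"level": 0.99, "reactions": ["R1"]},
    "evaluation": {
        "n_distributions": 8,
        "n_permutations": 200,
        "thresholds": [0.3, 0.85],
        "n_starts": 2,
    },
}


def default_config() -> dict:
    return copy.deepcopy(_DEFAULTS)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = default_config()
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _merge(cfg, loaded)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds spawned from the master seed."""
    children = np.random.SeedSequence(master_seed).spawn(len(STAGES) + 1)
    out = {stage: int(c.generate_state(1)[0] % 2**31) for stage, c in zip(STAGES, children)}
    out["scenario"] = int(children[-1].generate_state(1)[0] % 2**31)
    return out
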