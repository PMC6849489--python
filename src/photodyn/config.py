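"""Run configuration: YAML files with strict key checking.

Every tunable default of the pipeline can be overridden from one YAML
file with sections ``model``, ``phase``, ``training``, ``sampling``,
``dynamics`` and ``optimization`` plus a global ``seed``.  Unknown keys
are rejected so typos fail loudly, and every CLI run stores a fully
resolved copy of its configuration next to its outputs.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .errors import InvalidInputError

DEFAULTS: dict = {
    "seed": 0,
    "model": {
        "name": "avoided_crossing",
        "randomize_phase": False,
        "rng_seed": 0,
        "params": {},
    },
    "phase": {
        "decision_threshold": 0.5,
        "max_bisections": 10,
        "reference_index": 0,
    },
    "training": {
        "hidden": [50, 50],
        "learning_rate": 5e-3,
        "epochs": 3000,
        "eval_every": 25,
        "patience": 12,
        "val_fraction": 0.1,
        "loss_weights": {"energy": 1.0, "force": 1.0, "nac": 0.1,
                         "dipole": 0.1, "soc": 0.1},
    },
    "sampling": {
        "amplitudes": [-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0],
        "n_members": 2,
        "n_trajectories": 5,
        "safety_factor": 3.0,
        "decay": 0.95,
        "freeze_time_fs": 10000.0,
        "restart_on_trigger": True,
        "max_expansions": 200,
    },
    "dynamics": {
        "dt_fs": 0.5,
        "t_max_fs": 100.0,
        "n_traj": 10,
        "initial_state": None,   # default: highest state
        "sampling": "wigner",    # or "fixed"
        "n_substeps": 20,
        "decoherence": None,
        "rescale": "full",
    },
    "optimization": {
        "state": 0,
        "state_pair": [0, 1],
        "tol": 1e-5,
        "gap_tol": 1e-4,
        "sigma0": 3.5,
        "alpha": 0.02,
        "sigma_growth": 1.5,
    },
}


def _merge(defaults, override, path=""):
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise InvalidInputError(f"unknown configuration key: {where}")
        if isinstance(defaults[key], dict) and key != "params" \
                and key != "loss_weights":
            if not isinstance(value, dict):
                raise InvalidInputError(f"{where} must be a mapping")
            out[key] = _merge(defaults[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load and validate a config file, merged over the defaults."""
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise InvalidInputError(f"{path} does not contain a mapping")
    cfg = _merge(DEFAULTS, raw)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def save_config(path, cfg: dict) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
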