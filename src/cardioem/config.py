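"""Run configuration: schema-validated, all model constants overridable.

The configuration is a nested mapping (YAML on disk) with one block per
stage.  Unknown keys are rejected with their full path so typos cannot
silently fall back to defaults.  An empty file (or ``RunConfig()``) is the
all-defaults configuration used throughout the analysis.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "DEFAULTS"]

DEFAULTS: dict = {
    "seed": 0,
    "output_dir": "results",
    "log_level": "INFO",
    "cell": {
        "region": "epi",
        "cycle_length": 600.0,     # ms, sinus pacing
        "dt": 0.02,                # ms
        "overrides": {},           # named ionic-model constants
    },
    "tissue": {
        "dx": 0.025,               # cm
        "rho": 162.0,              # Ohm cm (70 cm/s preset)
        "S": 2000.0,               # 1/cm
        "Cm": 2.0,                 # uF/cm^2
        "dt": 0.02,                # ms
        "threshold": 0.0,          # mV activation threshold
    },
    "fixtures": {
        "cable": {"length": 2.0, "dx": 0.025},
        "shell": {"r_inner": 0.55, "r_outer": 0.80, "dx": 0.025,
                  "layers": [0.3, 0.4, 0.3]},
        "protocol": {"n_sites": 2, "onset": 20.0, "purkinje_speed": 200.0,
                     "seed": 2016, "amplitude": -52.0, "duration": 2.0,
                     "site_radius": 0.05},
    },
    "mechanics": {
        "ensemble_size": 128,
        "dt": 0.1,                 # ms
        "SL_ref": 2.15,            # um at V_SL_ref
        "V_SL_ref": 89.0,          # mL (LV)
        "V_SL_ref_rv": 110.0,      # mL (RV)
        "sl_feedback": True,       # SL follows cavity volume
        "force_len_lo": 1.55,      # um, zero-active-force length
        "force_len_hi": 1.95,      # um, saturation of the ascending limb
        "V_floor": 5.0,            # mL, wall-contact floor
        "series_rate": 0.03,       # um/ms per unit tension imbalance
        "series_recoil": 0.02,     # 1/ms, offset recoil rate
        "V_lv_init": 120.0,
        "V_rv_init": 120.0,
        "myofilament": {},         # named myofilament constants
    },
    "circulation": {
        "failing": True,           # -10% vascular compliances preset
        "R_av": 5.0, "R_mv": 8.0, "R_tv": 8.0, "R_pvalve": 10.0,
        "sa": {}, "sv": {}, "pa": {}, "pv": {},
        "lv": {}, "rv": {},        # ventricle-surrogate overrides
    },
    "sweep": {
        "conditions": [30.0, 40.0, 50.0, 60.0, 70.0],  # cm/s
        "electrical_duration": 3000.0,   # ms (5 cycles, last extracted)
        "n_cycles": 32,                  # mechanical cycles
        "calibration_tol": 0.01,
    },
}

_OPEN_BLOCKS = {
    ("cell", "overrides"), ("mechanics", "myofilament"),
    ("circulation", "sa"), ("circulation", "sv"), ("circulation", "pa"),
    ("circulation", "pv"), ("circulation", "lv"), ("circulation", "rv"),
}


def _merge(defaults: dict, user: dict, path: tuple = ()) -> dict:
    out = copy.deepcopy(defaults)
    errors = []
    for key, val in (user or {}).items():
        if key not in defaults:
            errors.append(".".join(path + (key,)))
            continue
        if isinstance(defaults[key], dict) and path + (key,) not in _OPEN_BLOCKS:
            if not isinstance(val, dict):
                raise ValueError(f"config block {'.'.join(path + (key,))} "
                                 f"must be a mapping")
            out[key] = _merge(defaults[key], val, path + (key,))
        else:
            out[key] = val
    if errors:
        raise KeyError("unknown config key(s): " + ", ".join(errors))
    return out


@dataclass
class RunConfig:
    """Validated effective configuration (defaults filled in)."""

    data: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    def __getattr__(self, name):
        d = object.__getattribute__(self, "data")
        if name in d:
            return d[name]
        raise AttributeError(name)

    @classmethod
    def from_dict(cls, user: dict | None) -> "RunConfig":
        return cls(data=_merge(DEFAULTS, user or {}))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.data, sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.data, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def echo(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        p = out / "effective_config.yaml"
        p.write_text(self.to_yaml())
        return p


def load_config(path) -> RunConfig:
    """Read and validate a YAML config file; empty file -> all defaults."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    user = yaml.safe_load(p.read_text())
    if user is None:
        user = {}
    if not isinstance(user, dict):
        raise ValueError("config root must be a mapping")
    return RunConfig.from_dict(user)
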