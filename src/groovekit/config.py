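"""Run configuration: structured YAML with strict key validation, defaults
echoed into a run manifest so every numeric convention is auditable."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["RunConfig", "RunManifest", "load_config", "default_helix_ranges"]

_DEFAULTS: dict = {
    "chain": "A",
    "features": {
        "water_radius": 3.0,
        "lipid_radius": 5.0,
        "occlusion_cutoff": 8.5,
        "tm3_tm4_cutoff": 3.5,
        "direct_contact_cutoff": 2.5,
        "include_hydrogens": False,
        "use_backbone_oxygen": False,
    },
    "tica": {"tau": 50, "k": 8, "seed": 0, "bins": 60},
    "pore": {
        "step": 0.25,
        "seed": 0,
        "z_window": None,
        "seed_point": None,     # default: V337/V447 CA midpoint
        "anchor_residue": 436,  # CA defines channel coordinate Z = 0
    },
    "pb": {
        "eps_protein": 2.0,
        "eps_core": 2.0,
        "eps_head": 30.0,
        "eps_water": 80.0,
        "core_thickness": 26.0,
        "headgroup_thickness": 8.0,
        "hole_radius": 18.0,
        "ionic_strength_mM": 150.0,
        "temperature": 298.0,
        "spacing": 0.8,
        "padding": 15.0,
        "tolerance": 1e-6,
        "include_membrane": True,
    },
    "kinetics": {
        "L_i_PF": 0.5,
        "gamma": 2.0,
        "n_starts": 8,
        "seed": 0,
        "bounds": {"f0": [0.0, 1.0], "alpha": [1e-6, 10.0], "beta": [1e-6, 10.0]},
    },
    "helices": None,  # path to a helix-range YAML; None -> packaged default
    "out_dir": "groovekit_out",
}


@dataclass
class RunConfig:
    values: dict

    def __getitem__(self, key):
        return self.values[key]

    def section(self, name: str) -> dict:
        return self.values[name]


@dataclass
class RunManifest:
    config: dict
    inputs: dict = field(default_factory=dict)
    version: str = ""
    seeds: dict = field(default_factory=dict)
    timestamp: str = ""

    def digest(self) -> str:
        payload = json.dumps(
            {"config": self.config, "inputs": self.inputs, "version": self.version},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def write(self, path: str | Path) -> None:
        data = asdict(self)
        data["manifest_hash"] = self.digest()
        Path(path).write_text(json.dumps(data, indent=1))


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    merged = {}
    for key, dval in defaults.items():
        if key in user:
            uval = user[key]
            if isinstance(dval, dict) and isinstance(uval, dict):
                merged[key] = _merge(dval, uval, f"{path}{key}.")
            else:
                merged[key] = uval
        else:
            merged[key] = dval
    unknown = set(user) - set(defaults)
    if unknown:
        raise ValueError(
            f"unknown config keys: {sorted(path + k for k in unknown)}"
        )
    return merged


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML run config; unknown keys are rejected and
    every defaulted parameter is materialized in the result."""
    user: dict = {}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        user = _merge_shallow(user, overrides)
    return RunConfig(values=_merge(_DEFAULTS, user))


def _merge_shallow(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge_shallow(out[k], v)
        else:
            out[k] = v
    return out


def default_helix_ranges(path: str | Path | None = None, chain: str = "A"):
    """TM helix ranges as ``[(chain, start, end), ...]`` plus the groove
    subset, from a YAML file or the packaged defaults."""
    if path is None:
        text = (resources.files("groovekit") / "data/helices.yaml").read_text()
    else:
        text = Path(path).read_text()
    data = yaml.safe_load(text)
    ranges = {
        name: (chain, int(lo), int(hi))
        for name, (lo, hi) in data["tm_helices"].items()
    }
    groove = [ranges[n] for n in data["groove_helices"]]
    return list(ranges.values()), groove
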