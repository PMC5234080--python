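"""Configuration file handling (JSON / YAML) for simulated experiments."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .illumination import GateBeam
from .simulate import SimConfig

__all__ = ["load_config", "dump_config", "config_schema"]

# Keys a config file may set.  'gate' is a nested mapping of GateBeam fields.
_SCALAR_KEYS = {
    "cell_size": "square cell side (um)",
    "density": "fluorescent particles per um^2",
    "D": "diffusion constant (um^2 s^-1)",
    "tau": "simulation time step (s); omit to derive from D",
    "oligomer_size": "fluorophores per particle",
    "photon_budget": "mean photons emitted before photobleaching",
    "emission_factor": "emitted photons per detected photon",
    "duration": "simulated time (s)",
    "roi_radius": "region-of-interest radius (um)",
    "seed": "random seed",
    "tirf_flux": "TIRF photon flux per fluorophore (s^-1)",
    "tirf_mode": "'roi_only' or 'whole_cell'; omit to derive from gate presence",
    "gate_frequency": "gate sweeps per second; omit or null for no gate (TOCCSL)",
    "dark_delay": "dark wait between pre-bleach and imaging (s)",
    "prebleach_passes": "stochastic pre-bleach passes; omit for exhaustive pre-bleach",
    "record_radius": "radius of the recorded region (um); omit for ROI + margin",
    "store_frames": "keep per-frame particle tables (needed for tracking)",
}
_GATE_KEYS = {"amplitude", "width", "ring_radius", "sweep_duration", "period"}


def load_config(path: str | Path) -> SimConfig:
    """Parse a JSON or YAML experiment config into a :class:`SimConfig`.

    An empty file yields all defaults.  Unknown keys and out-of-range values
    raise ``ValueError`` naming the offending keys.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return SimConfig()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        return SimConfig()
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return config_from_dict(data)


def config_from_dict(data: dict) -> SimConfig:
    unknown = sorted(set(data) - set(_SCALAR_KEYS) - {"gate"})
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    kwargs = {k: v for k, v in data.items() if k in _SCALAR_KEYS}
    gate_spec = data.get("gate")
    cfg = SimConfig(**kwargs)  # validates ranges, names offending keys
    if gate_spec is not None:
        bad = sorted(set(gate_spec) - _GATE_KEYS)
        if bad:
            raise ValueError(f"unknown gate keys: {', '.join(bad)}")
        cfg.gate = GateBeam(center=cfg.center, **gate_spec)
    return cfg


def dump_config(config: SimConfig, path: str | Path | None = None) -> dict:
    """Serialise a config (with derived fields resolved) to a dict, and
    optionally to a JSON or YAML file; ``load_config`` of the output
    reproduces the same resolved experiment."""
    d = config.to_dict()
    d["prebleach_passes"] = config.prebleach_passes
    d["store_frames"] = config.store_frames
    if d.get("gate") is not None:
        d.pop("gate_frequency", None)
    if path is not None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix.lower() == ".json":
                json.dump(d, fh, indent=2)
            else:
                yaml.safe_dump(d, fh)
    return d


def config_schema() -> dict:
    """Accepted config keys, their meaning, and the built-in defaults."""
    defaults = SimConfig()
    out = {}
    for key, desc in _SCALAR_KEYS.items():
        out[key] = {"description": desc, "default": getattr(defaults, key)}
    out["gate"] = {
        "description": "explicit gate beam (mapping with "
        + ", ".join(sorted(_GATE_KEYS))
        + "); overrides gate_frequency",
        "default": None,
    }
    return out
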