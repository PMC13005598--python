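"""YAML configuration loading and run manifests.

Config keys mirror the model's tunables::

    optics:
      mu_a: 0.1        # cm^-1
      mu_s: 220.0      # cm^-1
      g: 0.9
    dual_source:
      n: 10
      boundary_factor: 1.0
      literal_diffusion_const: true

Precedence is CLI flag > config file > built-in default.
"""

from __future__ import annotations

import getpass
import json
import platform
import time
from pathlib import Path

import yaml

from .optics import OpticalProperties

__all__ = ["load_config", "optics_from_config", "write_manifest", "DEFAULTS"]

DEFAULTS: dict = {
    "optics": {"mu_a": 0.1, "mu_s": None, "g": 0.9},
    "dual_source": {"n": 10.0, "boundary_factor": 1.0, "literal_diffusion_const": True},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config merged over the built-in defaults."""
    cfg = DEFAULTS
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError("config must be a YAML mapping")
        cfg = _deep_merge(cfg, user)
    return cfg


def optics_from_config(cfg: dict) -> OpticalProperties:
    opt = cfg["optics"]
    if opt.get("mu_s") is None:
        raise ValueError("config optics.mu_s is required")
    return OpticalProperties(mu_a=opt["mu_a"], mu_s=opt["mu_s"], g=opt["g"])


def write_manifest(
    out_dir: str | Path,
    command: str,
    resolved_config: dict,
    seeds: list[int] | None,
    outputs: list[str],
    wall_time_s: float,
) -> Path:
    """Record what a run did, next to its outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        user = getpass.getuser()
    except (KeyError, OSError):
        user = "unknown"
    manifest = {
        "command": command,
        "config": resolved_config,
        "seeds": seeds,
        "version": __version__,
        "outputs": outputs,
        "wall_time_s": round(wall_time_s, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "platform": platform.platform(),
        "user": user,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
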