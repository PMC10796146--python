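"""Run configuration loading and model construction for the CLI.

Configs are TOML (human-editable) or JSON with identical structure; all RNG
seeds are explicit.  A run's emitted ``meta.json`` embeds the resolved config
under ``"config"`` and is itself accepted as a config file, which is what
makes every run directory re-executable.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import numpy as np

from .core import MonitorSpec
from .errors import ConfigError
from .toolbox import section_input
from .zoo import (
    CANNNetwork,
    CANNParams,
    FHNNode,
    FHNParams,
    LIFParams,
    LIFPopulation,
    build_coba,
)

__all__ = ["load_config", "build_model", "build_inputs", "build_monitors"]


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        if path.suffix == ".toml":
            cfg = tomllib.loads(path.read_text())
        elif path.suffix == ".json":
            cfg = json.loads(path.read_text())
        else:
            raise ConfigError(f"unsupported config format {path.suffix!r}")
    except (tomllib.TOMLDecodeError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a table/object")
    # emitted run metadata embeds the original config under "config"
    if "config" in cfg and isinstance(cfg["config"], dict):
        cfg = cfg["config"]
    return cfg


def _params_from(section: dict, cls, allowed: set):
    kwargs = {k: v for k, v in section.items() if k in allowed}
    return cls(**kwargs)


def build_model(model_cfg: dict):
    """Instantiate a model-zoo network from its config section."""
    if "zoo" not in model_cfg:
        raise ConfigError("model section needs a 'zoo' entry")
    kind = model_cfg["zoo"]
    params = model_cfg.get("params", {})
    try:
        if kind == "lif":
            lif = _params_from(params, LIFParams,
                               {"tau", "V_rest", "V_reset", "V_th", "R", "t_ref"})
            return LIFPopulation(n=model_cfg.get("n", 1), params=lif)
        if kind == "fhn":
            fhn = _params_from(params, FHNParams, {"a", "b", "tau", "Iext"})
            return FHNNode(params=fhn,
                           v0=model_cfg.get("v0", 0.0), w0=model_cfg.get("w0", 0.0))
        if kind == "cann":
            cp = _params_from(params, CANNParams,
                              {"N", "tau", "k", "a", "J0", "L"})
            return CANNNetwork(params=cp)
        if kind == "coba":
            return build_coba(**params)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid parameters for model {kind!r}: {exc}") from exc
    raise ConfigError(f"unknown zoo model {kind!r}")


def build_inputs(inputs_cfg: dict, dt: float) -> dict:
    """Input arrays/scalars from config: constants or section programs."""
    out = {}
    for name, spec in (inputs_cfg or {}).items():
        if not isinstance(spec, dict):
            raise ConfigError(f"input {name!r} must be a table")
        if "constant" in spec:
            out[name] = float(spec["constant"])
        elif "sections" in spec:
            out[name] = section_input(
                [(float(v), float(d)) for v, d in spec["sections"]], dt
            )
        else:
            raise ConfigError(f"input {name!r} needs 'constant' or 'sections'")
    return out


def build_monitors(monitor_cfg) -> list:
    specs = []
    for entry in monitor_cfg or []:
        if isinstance(entry, str):
            specs.append(MonitorSpec(entry))
        elif isinstance(entry, (list, tuple)) and len(entry) == 2:
            specs.append(MonitorSpec(str(entry[0]), int(entry[1])))
        else:
            raise ConfigError(f"bad monitor entry {entry!r}")
    if not specs:
        raise ConfigError("at least one monitor is required")
    return specs
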