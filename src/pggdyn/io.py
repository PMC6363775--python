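"""Config loading and report writers (YAML/JSON configs, CSV/JSON outputs)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .model import ModelParams

__all__ = ["load_config", "dump_config", "params_from_config", "write_json", "write_trajectory"]


def load_config(path) -> dict:
    """Read a YAML (or JSON — YAML is a superset) config file into a dict."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def dump_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def params_from_config(cfg: dict) -> ModelParams:
    """Build ModelParams from a config dict with a ``params`` block (or flat keys)."""
    block = cfg.get("params", cfg)
    return ModelParams.from_dict(block)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n")


def write_trajectory(traj, path, sidecar: dict | None = None) -> None:
    """CSV with columns time, x_C, x_D, y, Y plus a JSON metadata sidecar."""
    path = Path(path)
    traj.to_frame().to_csv(path, index=False)
    meta = {"params": traj.params.to_dict()}
    if sidecar:
        meta.update(sidecar)
    write_json(meta, path.with_suffix(".meta.json"))
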