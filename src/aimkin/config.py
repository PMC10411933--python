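"""YAML configuration: one file fully determines a run.

The config carries the scene geometry, performer parameters, segmentation
constants and screening thresholds; defaults reproduce the task constants
(0.5 au/s onset threshold, 30 ms staircase step, 300/1,500 ms starts,
0.4/0.6/0.8 au distances, 45 deg angle grid, 1 au workspace cap, 95%
ellipse coverage, 3 MADs with consistency 1.4826, 30 fps minimum and 10 fps
maximum difference/drop).
"""

from __future__ import annotations

import yaml

from .contexts import SceneConfig
from .performer import PerformerParams

__all__ = ["default_config", "load_config", "save_config", "scene_from_config", "params_from_config"]


def default_config() -> dict:
    return {
        "scene": SceneConfig().to_dict(),
        "performer": PerformerParams().to_dict(),
        "segmentation": {
            "threshold": 0.5,       # au/s, movement-onset radial speed
            "peak_frac": 0.5,       # primary end: local-min fraction of peak
            "window": 1,            # samples, speed moving average (odd; 1 = off)
        },
        "staircase": {
            "step": 30.0,           # ms
            "starts": {"low": 300.0, "high": 1500.0},
            "analysis_window": 40,  # trials per staircase
        },
        "screening": {
            "min_fps": 30.0,
            "max_fps_diff": 10.0,
            "success_tolerance": 0.10,
            "mad_k": 3.0,
            "mad_consistency": 1.4826,
        },
        "ellipse_coverage": 0.95,
    }


def load_config(path=None) -> dict:
    """Defaults, deep-updated by the YAML file at ``path`` (if given)."""
    cfg = default_config()
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def scene_from_config(cfg: dict) -> SceneConfig:
    return SceneConfig(**cfg.get("scene", {}))


def params_from_config(cfg: dict) -> PerformerParams:
    p = dict(cfg.get("performer", {}))
    if p.get("angle_bias") is not None:
        p["angle_bias"] = tuple(tuple(pair) for pair in p["angle_bias"])
    return PerformerParams(**p)
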