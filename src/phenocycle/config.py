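"""TOML configuration: sections [reconstruction], [cycles], [model], [raster]."""

from __future__ import annotations

import tomllib

from .cycles import CycleThresholds
from .series import ReconstructionConfig

__all__ = ["load_config", "reconstruction_from_config", "thresholds_from_config"]


def load_config(path) -> dict:
    if path is None:
        return {}
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def reconstruction_from_config(config: dict) -> ReconstructionConfig:
    sec = config.get("reconstruction", {})
    return ReconstructionConfig(
        jump_threshold=sec.get("jump_threshold", 0.4),
        sg_window=sec.get("sg_window", 3),
        sg_polyorder=sec.get("sg_polyorder", 2),
        max_fill_iterations=sec.get("max_fill_iterations", 10),
    )


def thresholds_from_config(config: dict) -> CycleThresholds:
    sec = config.get("cycles", {})
    return CycleThresholds(
        vegetation_floor=sec.get("vegetation_floor", 0.3),
        peak_fraction=sec.get("peak_fraction", 0.70),
        valley_fraction=sec.get("valley_fraction", 0.20),
    )
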