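"""Key-value configuration with package defaults.

A YAML file overrides any subset of the defaults; unknown keys are
rejected early so typos fail loudly.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "slo": {
        "threshold_t": None,          # None -> percentile rule
        "threshold_percentile": 98.0,
        "disk_s": 15,
        "disk_t": 5,
        "smooth_window": 11,
    },
    "tracker": {
        "kernel_s": None,             # None -> X/8
        "peak_factor": 0.5,
        "max_step": 50.0,
        "rollback_bscans": 4,
        "epsilon": 1e-9,
        "absolute_floor": 0.02,
        "bscans_per_frame": 1.14,
        "max_retakes": 100,
    },
    "segmentation": {
        "top_fraction": 0.5,
        "close_radius": 1,
        "min_area": 50,
        "smooth_window": 101,
        "gradient_kernel": 15,
    },
    "projection": {
        "band_um": 30.0,
        "repeat_peak_threshold": 0.03,
    },
    "registration": {
        "levels_n": 3,
        "min_part_px": 64,
        "keep_fraction": 0.7,
        "pad_px": 128,
        "k_grid": [-0.1, -0.05, 0.0, 0.05, 0.1, 0.15, 0.2],
    },
    "stitch": {
        "weighted": True,
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key not in base:
            raise KeyError(f"unknown config key {path + key!r}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _merge(base[key], val, path + key + ".")
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _merge(DEFAULTS, data)
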