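"""Default configuration and YAML loading.

Every tunable constant of the annotation pipeline lives here under a
named key so studies are reproducible from a single YAML file.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any

import yaml

__all__ = ["DEFAULT_CONFIG", "default_config", "load_config", "merge_config"]

DEFAULT_CONFIG: dict[str, Any] = {
    "lowpass": {
        # zero-phase 4th-order Butterworth for pressure smoothing
        "cutoff_hz": 15.0,
        "order": 4,
    },
    "rest": {
        # windowed mean-squared energy of the max-abs-normalized motion
        # channels; below threshold -> rest.  Calibrated on the bundled
        # synthetic generator defaults.
        "window_s": 0.10,
        "threshold": 0.01,
        "lowpass_hz": 20.0,
        "channels": ["GZ"],
    },
    "sync": {
        # insole-to-IMU resampling-ratio grid and lag search
        "ratio_min": 1.4,
        "ratio_max": 3.3,
        "ratio_step": 0.001,
        "max_lag_s": 1.0,
    },
    "edges": {
        # empirically chosen reconstruction of the edge-filtering rules
        "min_strength": 5.0,  # derivative peak magnitude, 1/s on [0,1] pressure
        "cluster_s": 0.10,
        "min_stance_s": 0.08,
        "min_swing_s": 0.08,
    },
    "features": {
        # window/step for the sliding-window feature extractor
        "window_s": 0.070,
        "step_s": 0.005,
    },
    "hhmm": {
        "n_iterations": 100,
        "em_iterations": 10,  # GMM density fitting
        "components": 1,  # Gaussians per internal state
        "variance_floor": 1e-6,
        "early_stop": True,
        "training_mode": "viterbi",
    },
    "pd": {
        # mid-swing peak picking on max-abs-normalized GZ
        "min_distance_s": 0.4,
        "min_height": 0.5,
    },
    "lce": {
        # local cyclicity estimation
        "noise_threshold": 1.0,
        "f_min_hz": 0.5,
        "f_max_hz": 6.0,
    },
    "postprocess": {
        "outlier_k": 3.0,
    },
    "eval": {
        "tolerance_s": 0.05,
        "require_label_match": False,
    },
    "study": {
        "n_batches": 7,
        "subjects_per_batch": 3,
        "holdout_subjects": 3,
        "noise_sd": 0.10,
        "seed": 0,
    },
}


def default_config() -> dict[str, Any]:
    """A deep copy of the package defaults."""
    return copy.deepcopy(DEFAULT_CONFIG)


def merge_config(base: dict[str, Any], override: dict[str, Any]) -> dict[str, Any]:
    """Recursively overlay ``override`` onto ``base`` (returns a new dict)."""
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = merge_config(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Package defaults overlaid with an optional user YAML file."""
    config = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        config = merge_config(config, user)
    return config
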