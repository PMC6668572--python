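"""Run configuration: a nested YAML document mirroring each stage's
parameters, with unknown keys rejected and stage seeds derived stably from
the global seed."""

from __future__ import annotations

import copy
import zlib

import numpy as np
import yaml

__all__ = ["DEFAULTS", "RunConfig", "load_config", "stage_seed"]

#: Full default configuration.  The sim section is the down-scaled preset
#: (same geometric ratios as the instrument, far fewer samples) so the
#: simulate -> prepare -> train -> evaluate chain runs quickly; the model
#: section is the matching scaled network.
DEFAULTS: dict = {
    "seed": 0,
    "output_dir": "runs/latest",
    "sim": {
        "repetition_rate": 3.66e7,
        "sampling_rate": 32 * 3.66e7,
        "flow_speed": 13.0,
        "fov_width_um": 25.0,
        "optical_resolution_um": 2.5,
        "n_elements": 100,
        "pulses_per_element": 64,
        "element_overlap": 0.5,
        "noise_sd": 0.02,
        "blank_fraction": 1.0 / 3.0,
        "class_mix": {"SW-480": 0.5, "OT-II": 0.5},
        "n_waveforms": 20,
    },
    "prep": {
        "n_elements": 100,
        "overlap": 0.5,
        "reduction_factor": 4,
        "standardize": True,
        "fractions": [0.8, 0.1, 0.1],
    },
    "model": {
        "conv_blocks": [[2, 16], [2, 32], [2, 64]],
        "fc_sizes": [1024, 64, 3],
        "dropout_keep_prob": 0.5514,
        "l2_multiplier": 0.00408,
    },
    "train": {
        "learning_rate": 1e-3,
        "n_epochs": 8,
        "batch_size": 64,
    },
    "search": {
        "l2_bounds": [1e-4, 1.0],
        "keep_prob_bounds": [0.0, 1.0],
        "l2_log_uniform": True,
        "n_trials_per_stage": 12,
        "stages": 2,
        "n_epochs": 2,
    },
    "realtime": {
        "flow_speed": 1.3,
        "batch_sizes": [1, 2, 4, 8, 16, 32, 64],
        "repetitions": 5,
        "margin": 0.0,
    },
}


class RunConfig(dict):
    """Plain nested dict with attribute-free section access."""

    def section(self, name: str) -> dict:
        return self[name]


def _merge(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in overrides.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            # class_mix keys are data, not schema
            if path.endswith("sim") and key == "class_mix":
                out[key] = value
                continue
            raise KeyError(f"unknown configuration key: {here}")
        if isinstance(defaults[key], dict) and key != "class_mix":
            if not isinstance(value, dict):
                raise ValueError(f"{here} must be a mapping")
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run config on top of the defaults; unknown keys raise."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    merged = _merge(DEFAULTS, data)
    if overrides:
        merged = _merge(merged, overrides)
    return RunConfig(merged)


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: stages are independently reproducible."""
    return int(np.random.SeedSequence(
        [int(global_seed), zlib.crc32(stage.encode())]
    ).generate_state(1)[0] % (2 ** 31))
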