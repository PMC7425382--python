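"""Declarative run configuration with YAML round-trip.

Every key has a default; a config file only needs the keys it overrides.
The effective configuration is serialised verbatim into each run's
output directory so a run can be reproduced from its own artifacts.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synth": {
        "sessions": 2,
        "fs": 1000.0,
        "duration_s": 180.0,
        "noise_scale": 1.1,
        "groups": [
            {
                "label": "patient",
                "n_subjects": 19,
                "rate_mean": 106.0,
                "rate_sd": 8.0,
                "noise_exponent": 0.8,
            },
            {
                "label": "control",
                "n_subjects": 19,
                "rate_mean": 120.0,
                "rate_sd": 11.0,
                "noise_exponent": 0.65,
            },
        ],
        "burst": {
            "duration_ms_mean": 75.0,
            "duration_ms_sd": 30.0,
            "duration_ms_min": 20.0,
            "amplitude_mean": 1.0,
            "amplitude_sd": 0.25,
            "freq_low": 15.0,
            "freq_high": 29.0,
        },
        "session_rate_offset": 0.0,
        "symptoms": {
            "midline_function": {"mean_score": 4.0, "pct_change_per_10": 0.0},
            "rest_tremor": {"mean_score": 3.0, "pct_change_per_10": 0.0},
            "rigidity": {"mean_score": 6.0, "pct_change_per_10": 0.0},
            "bradykinesia": {"mean_score": 13.0, "pct_change_per_10": -28.0},
            "postural_kinetic_tremor": {"mean_score": 3.0, "pct_change_per_10": -40.0},
            "lower_limb_bradykinesia": {"mean_score": 3.0, "pct_change_per_10": 0.0},
        },
        "signal_format": "binary",
    },
    "band": {"low": 13.0, "high": 30.0, "trans_low": 3.25, "trans_high": 7.5},
    "envelope": {"edge_trim_s": 1.0},
    "threshold": {
        "k": "auto",
        "k_min": 1.0,
        "k_max": 5.0,
        "k_step": 0.1,
        "segment_len_s": 3.0,
        "center": "median",
        "mode": "scaled",
    },
    "psd": {"seg_len_s": 3.0, "overlap": 0.5, "fmin": 1.0, "fmax": 48.0},
    "fit": {"max_peaks": 8},
    "stats": {"bootstrap_n": 0},
    "roc": {"criterion": "youden"},
    "sweep": {"enabled": True, "k_step": 0.1},
}


def _deep_update(base: dict, override: dict) -> dict:
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, optionally updated from a YAML file and a dict."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        _deep_update(config, loaded)
    if overrides:
        _deep_update(config, overrides)
    return config


def save_config(config: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config, sort_keys=False))
    return path


def groups_from_config(config: dict):
    """Materialise GroupSpec objects from the synth section."""
    from .simulate import BurstGenSpec, GroupSpec, NoiseGenSpec

    synth = config["synth"]
    burst = BurstGenSpec(**synth["burst"])
    groups = []
    for g in synth["groups"]:
        noise = NoiseGenSpec(
            exponent=g.get("noise_exponent", 0.8),
            scale=synth["noise_scale"],
            fs=synth["fs"],
            duration_s=synth["duration_s"],
        )
        groups.append(
            GroupSpec(
                label=g["label"],
                n_subjects=int(g["n_subjects"]),
                rate_mean=float(g["rate_mean"]),
                rate_sd=float(g["rate_sd"]),
                noise=noise,
                burst=burst,
                session_rate_offset=float(synth.get("session_rate_offset", 0.0)),
            )
        )
    return groups


def symptom_specs_from_config(config: dict):
    import numpy as np

    from .simulate import SymptomGenSpec

    ref_rate = 106.0
    specs = {}
    for name, entry in config["synth"]["symptoms"].items():
        specs[name] = SymptomGenSpec(
            intercept_log=float(np.log(entry["mean_score"])),
            pct_change_per_10=float(entry["pct_change_per_10"]),
            ref_rate=ref_rate,
        )
    return specs
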