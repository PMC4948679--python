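"""Configuration schema for the command-line workflow.

A single YAML file carries the structured inputs (region definitions,
threshold vector, file lists); command-line flags override individual
keys.  Every analysis default is defined here in one place and echoed to
the log at run time.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .structure_io import ALL, BACKBONE_ATOMS, RegionSelection

DEFAULTS = {
    "chain": "H",
    "thresholds_nm": [0.05, 0.10, 0.15, 0.20],
    "cutoff_nm": 0.2,
    "significance_threshold": 0.20,
    "start_fraction": 0.2,
    "stride": 1,
    "temperature_K": 293.0,
    "r2_threshold": 0.8,
    "outlier_window_kj": 5.6,
    "cdr_mutants": [],
}

_REQUIRED_REGION_KEYS = ("fr3_range", "fr4_range", "cdr3_range")


class ConfigError(ValueError):
    """Configuration problem, reported with the offending key path."""


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    cfg = dict(DEFAULTS)
    cfg.update(raw)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    for key in _REQUIRED_REGION_KEYS:
        if key not in cfg:
            raise ConfigError(f"missing required key: {key}")
        rng = cfg[key]
        if (not isinstance(rng, (list, tuple)) or len(rng) != 2
                or int(rng[0]) > int(rng[1])):
            raise ConfigError(f"{key}: expected [first, last] with "
                              f"first <= last, got {rng!r}")
    c = cfg["thresholds_nm"]
    if not c or any(b <= a for a, b in zip(c, c[1:])) or c[0] <= 0:
        raise ConfigError("thresholds_nm: must be a strictly increasing "
                          "list of positive values")
    if not (0.0 <= float(cfg["start_fraction"]) <= 1.0):
        raise ConfigError("start_fraction: must lie in [0, 1]")
    if int(cfg["stride"]) < 1:
        raise ConfigError("stride: must be >= 1")
    if float(cfg["cutoff_nm"]) <= 0:
        raise ConfigError("cutoff_nm: must be positive")


def region_selection(cfg: dict) -> RegionSelection:
    """Fit on FR3+FR4 backbone, RMSD on all CDR3 atoms."""
    chain = str(cfg["chain"])
    return RegionSelection(
        fit_region=[(chain, tuple(cfg["fr3_range"]), BACKBONE_ATOMS),
                    (chain, tuple(cfg["fr4_range"]), BACKBONE_ATOMS)],
        rmsd_region=[(chain, tuple(cfg["cdr3_range"]), ALL)],
    )
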