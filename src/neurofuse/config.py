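"""Run configuration: defaults table, YAML loading, provenance records.

One table (``DEFAULTS``) centralizes every tunable shared by the library
and the command line, so the two cannot drift.  ``parse_config`` merges a
YAML file with flag overrides (flags win), rejecting unknown keys with a
nearest-match suggestion.  Every CLI run writes a provenance JSON — the
resolved configuration, the package version and SHA-256 checksums of the
inputs — sufficient to re-run the analysis bit-identically.
"""

from __future__ import annotations

import difflib
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ContractError

__all__ = ["DEFAULTS", "RunConfig", "parse_config", "write_provenance"]

DEFAULTS: dict = {
    "seed": 0,
    "tr": 2.0,
    "out_dir": ".",
    "log_level": "info",
    "jobs": 1,
    # denoising
    "motion_scheme": 24,
    "band": [0.01, 0.08],
    "global_signal": False,
    "hp_cutoff_s": 128.0,
    # FCD / FOCA
    "thresholds": [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8],
    "connectivity": 26,
    "window": 40,
    "step": 1,
    "mask_fraction": 0.2,
    # EEG
    "eeg_band": [1.0, 30.0],
    "filter_method": "fir",
    "power_band": [8.0, 12.0],
    # regressors / GLM
    "hrf": "spm_canonical",
    "hrf_peak": 5.0,
    "peaks": [3.0, 5.0, 7.0, 9.0],
    "microtime_bins": 16,
    # LMSA
    "max_lag": 6,
    "alpha": 0.05,
}


@dataclass
class RunConfig:
    subcommand: str
    params: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.params[key]

    def get(self, key, default=None):
        return self.params.get(key, default)


def _reject_unknown(keys) -> None:
    for key in keys:
        if key not in DEFAULTS:
            hint = difflib.get_close_matches(key, DEFAULTS, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ContractError(f"unknown config key {key!r}{suffix}")


def parse_config(subcommand: str, config_path=None, **flag_overrides) -> RunConfig:
    """Merge defaults, a YAML config file and explicit flags (flags win)."""
    params = dict(DEFAULTS)
    if config_path is not None:
        raw = yaml.safe_load(Path(config_path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ContractError(f"config {config_path} must be a mapping")
        _reject_unknown(raw)
        params.update(raw)
    overrides = {k: v for k, v in flag_overrides.items() if v is not None}
    _reject_unknown(overrides)
    params.update(overrides)
    return RunConfig(subcommand=subcommand, params=params)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(out_dir, config: RunConfig, inputs=()) -> Path:
    """Record config + version + input checksums next to the outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "tool": "neurofuse",
        "version": __version__,
        "subcommand": config.subcommand,
        "params": config.params,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
    }
    path = out_dir / f"provenance_{config.subcommand}.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True, default=str))
    return path
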