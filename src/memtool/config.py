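"""Run configuration: defaults, YAML config files, and flag precedence.

Every CLI subcommand resolves its parameters through :func:`resolve_config`:
documented defaults first, then values from an optional YAML config file,
then command-line flags (flags win).  Unknown keys are rejected with a
spelling suggestion, and the fully resolved parameter set is logged next to
each run's output so any artifact can be regenerated from its log.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "DEFAULTS", "resolve_config"]

DEFAULTS: dict[str, dict] = {
    "analyze.isotherm": {
        "smooth_window": 11,
        "smooth_order": 3,
        "search_low": 10.0,
        "search_high": 30.0,
    },
    "analyze.insertion": {},
    "analyze.atr": {
        "n1": 3.42,
        "n2": 1.42,
        "angle": 60.0,
        "n_film": None,
        "wavenumber": 2900.0,
    },
    "analyze.eis": {"ref_c": None},
    "analyze.traj": {
        "cutoff": 12.0,
        "d_max": 3.5,
        "angle_min": 135.0,
        "bin_width_A": 1.0,
        "bin_width_deg": 2.0,
        "n_closest": 6,
        "fold": False,
        "absolute": False,
        "reconstruct_h": False,
        "sel_a": "probe",
        "sel_b": "lipids",
        "donors": "donors",
        "acceptors": "acceptors",
        "chains": "chains",
    },
    "simulate.isotherm": {
        "moduli": [100.0, 5.0, 200.0],
        "plateau_pressure": 20.0,
        "plateau_width": 1.0,
        "pi_start": 0.5,
        "pi_max": 45.0,
        "n_points": 400,
        "area_start": 100.0,
        "area_shift": 0.0,
        "noise_sigma": 0.05,
    },
    "simulate.insertion": {
        "pi0_values": [10.0, 15.0, 20.0, 25.0, 30.0],
        "slope": -0.2,
        "intercept": 10.5,
        "beta": 0.01,
        "duration": 600.0,
        "n_points": 600,
        "noise_sigma": 0.05,
    },
    "simulate.atr": {
        "n1": 3.42,
        "n2": 1.42,
        "angle": 60.0,
        "n_film": None,
        "noise_sigma": 1e-4,
        "orientation_sd": None,
    },
    "simulate.eis": {
        "frequency": 25.0,
        "c_min": 1.44,
        "e_min": -0.6,
        "curvature": 0.15,
        "defect_peak": None,
        "noise_sigma_ohm": 1.0,
    },
    "simulate.traj": {
        "n_lipids_per_leaflet": 8,
        "n_carbons": 9,
        "n_frames": 100,
        "tilt_mean": 33.0,
        "tilt_sd": 5.0,
        "lattice_spacing": 10.0,
        "format": "pdb",
    },
}


@dataclass
class RunConfig:
    """Fully resolved parameters for one CLI run."""

    subcommand: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    verbosity: int = 0

    def log_dict(self) -> dict:
        from . import __version__

        return {
            "subcommand": self.subcommand,
            "version": __version__,
            "seed": self.seed,
            "params": self.params,
        }


def resolve_config(
    subcommand: str,
    config_path: str | Path | None = None,
    overrides: dict | None = None,
    seed: int = 0,
    verbosity: int = 0,
) -> RunConfig:
    """Merge defaults, a YAML config file and flag overrides (flags win).

    Raises ``ValueError`` naming any unknown key, with a closest-match
    suggestion, and on type mismatches against the documented default.
    """
    if subcommand not in DEFAULTS:
        raise ValueError(f"unknown subcommand {subcommand!r}")
    params = dict(DEFAULTS[subcommand])
    if config_path is not None:
        raw = yaml.safe_load(Path(config_path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{config_path}: config must be a mapping")
        _merge(params, raw, subcommand, source=str(config_path))
    if overrides:
        _merge(params, {k: v for k, v in overrides.items() if v is not None},
               subcommand, source="flags")
    return RunConfig(subcommand=subcommand, params=params, seed=seed, verbosity=verbosity)


def _merge(params: dict, new: dict, subcommand: str, source: str) -> None:
    for key, value in new.items():
        if key not in params:
            hint = difflib.get_close_matches(key, params.keys(), n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown key {key!r} in {source}{suggestion}")
        default = params[key]
        if default is not None and value is not None:
            if isinstance(default, bool) != isinstance(value, bool):
                raise ValueError(f"key {key!r} in {source}: expected bool, got {type(value).__name__}")
            if isinstance(default, (int, float)) and not isinstance(value, (int, float)):
                raise ValueError(
                    f"key {key!r} in {source}: expected number, got {type(value).__name__}"
                )
            if isinstance(default, str) and not isinstance(value, str):
                raise ValueError(f"key {key!r} in {source}: expected string, got {type(value).__name__}")
            if isinstance(default, (list, tuple)) and not isinstance(value, (list, tuple)):
                raise ValueError(f"key {key!r} in {source}: expected list, got {type(value).__name__}")
        params[key] = value
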