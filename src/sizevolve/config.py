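"""YAML configuration loading with documented defaults.

An empty file (or no file) yields the default configuration: control
structure (G1 size control, S/G2/M timer of 0.54 tau), quantity sensing,
growth rate 0.5 per time unit.  The ``structure`` key accepts the named
presets ``control``, ``pombe`` (inverted cycle), ``g1long`` (short
0.36 tau timer) and ``g1short`` (long 0.72 tau timer); an explicit
``timer_fraction`` overrides the preset's.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .simulator import (CycleConfig, HazardParams, STRUCTURE_CONTROL,
                        STRUCTURE_POMBE)


class ConfigError(ValueError):
    pass


#: structure preset -> (cycle structure, timer fraction)
STRUCTURE_PRESETS = {
    "control": (STRUCTURE_CONTROL, 0.54),
    "pombe": (STRUCTURE_POMBE, 0.54),
    "g1long": (STRUCTURE_CONTROL, 0.36),
    "g1short": (STRUCTURE_CONTROL, 0.72),
}

_CONFIG_KEYS = {"growth_rate", "structure", "sensing", "timer_fraction",
                "timer_noise_width", "growth_cv", "partition_cv",
                "molecular_noise", "omega0", "hazard", "V_min", "V_max",
                "V_init", "dt", "T_total", "warmup_cycles"}
_HAZARD_KEYS = {"h_max", "K_h", "n_h"}
_EVOLUTION_KEYS = {"epochs", "population_size", "mode", "objectives",
                   "checkpoint_every"}

DEFAULT_EVOLUTION = {"epochs": 100, "population_size": 50, "mode": "pareto",
                     "objectives": ["ndiv", "cv_birth"],
                     "checkpoint_every": 50}


def config_from_mapping(doc: dict | None) -> tuple[CycleConfig, dict]:
    """Build (CycleConfig, evolution settings) from a parsed mapping."""
    doc = dict(doc or {})
    evo = dict(DEFAULT_EVOLUTION)
    evo_doc = doc.pop("evolution", {}) or {}
    unknown = set(evo_doc) - _EVOLUTION_KEYS
    if unknown:
        raise ConfigError(f"unknown evolution keys {sorted(unknown)}")
    evo.update(evo_doc)
    if evo["mode"] not in ("pareto", "ndiv"):
        raise ConfigError(f"unknown evolution mode {evo['mode']!r}")

    unknown = set(doc) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys {sorted(unknown)}")

    kw = dict(doc)
    structure = kw.pop("structure", "control")
    if structure not in STRUCTURE_PRESETS:
        raise ConfigError(
            f"unknown structure {structure!r}; choose from "
            f"{sorted(STRUCTURE_PRESETS)}")
    cycle_structure, preset_ft = STRUCTURE_PRESETS[structure]
    kw.setdefault("timer_fraction", preset_ft)
    hz = kw.pop("hazard", None)
    if hz is not None:
        unknown = set(hz) - _HAZARD_KEYS
        if unknown:
            raise ConfigError(f"unknown hazard keys {sorted(unknown)}")
        kw["hazard"] = HazardParams(**hz)
    try:
        config = CycleConfig(structure=cycle_structure, **kw).validate()
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return config, evo


def load_config(path: str | Path | None) -> tuple[CycleConfig, dict]:
    """Load a YAML config file; every unset field takes its default."""
    if path is None:
        return config_from_mapping({})
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    doc = yaml.safe_load(path.read_text())
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError("config file must contain a mapping")
    return config_from_mapping(doc)


def resolved_config_dict(config: CycleConfig, evolution: dict | None = None,
                         seed: int | None = None) -> dict:
    """Fully-resolved settings, for echoing into output directories."""
    d = asdict(config)
    d["tau"] = config.tau
    if evolution is not None:
        d["evolution"] = dict(evolution)
    if seed is not None:
        d["seed"] = seed
    return d
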