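"""Durable outputs: lineage tables, evolution logs, period curves.

Everything is written as tidy CSV plus a JSON/YAML summary; existing
files are never overwritten without an explicit flag, and each output
directory receives a copy of the fully-resolved configuration and an
append-only log line with timestamp and seed.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import yaml

from .analysis import PeriodCurve
from .config import resolved_config_dict
from .evolution import EvolutionTrajectory
from .simulator import CYCLE_COLUMNS, CycleConfig, LineageRecord


class OutputError(RuntimeError):
    pass


def _check_writable(directory: Path, names: list[str], overwrite: bool):
    directory.mkdir(parents=True, exist_ok=True)
    if not overwrite:
        clashes = [n for n in names if (directory / n).exists()]
        if clashes:
            raise OutputError(
                f"refusing to overwrite {clashes} in {directory}; "
                f"pass overwrite=True (--force) to allow")


def _log_line(directory: Path, message: str, seed: int | None):
    stamp = datetime.datetime.now().isoformat(timespec="seconds")
    with open(directory / "run.log", "a") as fh:
        fh.write(f"{stamp}\tseed={seed}\t{message}\n")


def write_outputs(obj, directory: str | Path, config: CycleConfig | None = None,
                  seed: int | None = None, prefix: str = "",
                  overwrite: bool = False) -> list[Path]:
    """Write a lineage record, evolution trajectory or period curve.

    Returns the list of files written.  The resolved configuration is
    echoed as ``config.yaml`` so every output directory is
    self-describing.
    """
    directory = Path(directory)
    written: list[Path] = []

    if isinstance(obj, LineageRecord):
        names = [f"{prefix}cycles.csv"]
        if obj.trace is not None:
            names.append(f"{prefix}trace.csv")
        _check_writable(directory, names, overwrite)
        cols = [c for c in CYCLE_COLUMNS if c in obj.cycles.columns]
        extra = [c for c in obj.cycles.columns if c not in cols]
        obj.cycles[cols + extra].to_csv(directory / names[0], index=False)
        written.append(directory / names[0])
        if obj.trace is not None:
            obj.trace.to_csv(directory / names[-1], index=False)
            written.append(directory / names[-1])
        summary = {"n_divisions": obj.n_divisions, "died": obj.died,
                   "capped": obj.capped, "t_end": obj.t_end}
        (directory / f"{prefix}summary.json").write_text(
            json.dumps(summary, indent=2))
        written.append(directory / f"{prefix}summary.json")
        config = config or obj.config

    elif isinstance(obj, EvolutionTrajectory):
        names = [f"{prefix}evolution_log.csv"]
        _check_writable(directory, names, overwrite)
        obj.log.to_csv(directory / names[0], index=False)
        written.append(directory / names[0])
        ckpt_dir = directory / f"{prefix}checkpoints"
        ckpt_dir.mkdir(exist_ok=True)
        for epoch, doc in obj.checkpoints.items():
            p = ckpt_dir / f"epoch_{epoch:05d}_rank1.json"
            p.write_text(doc)
            written.append(p)

    elif isinstance(obj, PeriodCurve):
        names = [f"{prefix}period_curve.csv"]
        _check_writable(directory, names, overwrite)
        obj.to_frame().to_csv(directory / names[0], index=False)
        written.append(directory / names[0])

    else:
        raise OutputError(f"do not know how to write {type(obj).__name__}")

    if config is not None:
        (directory / "config.yaml").write_text(
            yaml.safe_dump(resolved_config_dict(config, seed=seed)))
    _log_line(directory, f"wrote {[p.name for p in written]}", seed)
    return written
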