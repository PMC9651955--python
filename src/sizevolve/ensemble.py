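"""Ensembles of independent evolutionary runs.

Structural comparisons (which cycle structure biases evolution toward
sizers or adders) rest on many independent evolution runs per condition;
this module orchestrates them with derived seeds
(base_seed + run index) and extracts the two scatter coordinates used to
summarize each run's fittest network: the birth-size CV and the fitted
added-volume slope over the whole cycle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .analysis import AnalysisError, birth_cv, fit_phase_slopes
from .evolution import run_evolution
from .network import NetworkSpec
from .simulator import CycleConfig, SimulationError, simulate_lineage

ENSEMBLE_COLUMNS = ["run_id", "mode", "structure", "slope_cycle",
                    "cv_birth", "epochs", "seed"]


def summarize_best(network: NetworkSpec, config: CycleConfig,
                   seed: int, min_cycles: int = 150) -> tuple[float, float]:
    """(cycle ΔV slope, CVBirth) of a network on a fresh long lineage."""
    tau = config.tau
    long_cfg = config.replace(
        T_total=max(config.T_total, (min_cycles + config.warmup_cycles) * tau * 1.5))
    rec = simulate_lineage(network, long_cfg, seed=seed)
    slope = fit_phase_slopes(rec, "cycle").slope
    return float(slope), float(birth_cv(rec))


def run_ensemble(seed_network: NetworkSpec, config: CycleConfig,
                 n_runs: int, mode: str = "pareto", base_seed: int = 0,
                 epochs: int = 100, population_size: int = 50,
                 structure_label: str | None = None) -> pd.DataFrame:
    """Run ``n_runs`` independent evolutions and summarize each.

    Seeds derive as ``base_seed + run_index`` so runs are independent yet
    individually reproducible.  ``mode`` is ``"pareto"`` (NDiv + CVBirth)
    or ``"ndiv"`` (single objective).  Per-run failures are recorded as
    NaN rows; the ensemble continues.
    """
    if n_runs < 1:
        raise ValueError("need at least one run")
    if mode not in ("pareto", "ndiv"):
        raise ValueError(f"unknown ensemble mode {mode!r}")
    label = structure_label or config.structure
    objectives = ("ndiv", "cv_birth") if mode == "pareto" else ("ndiv",)
    sel_mode = "pareto" if mode == "pareto" else "single"
    rows = []
    for run in range(n_runs):
        run_seed = base_seed + run
        row = {"run_id": run, "mode": mode, "structure": label,
               "slope_cycle": np.nan, "cv_birth": np.nan,
               "epochs": epochs, "seed": run_seed}
        try:
            traj = run_evolution(seed_network, config, epochs=epochs,
                                 population_size=population_size,
                                 objectives=objectives, mode=sel_mode,
                                 seed=run_seed)
            best = traj.best
            row["slope_cycle"], row["cv_birth"] = summarize_best(
                best.network, config, seed=run_seed + 10_000)
        except (SimulationError, AnalysisError):
            pass
        rows.append(row)
    return pd.DataFrame(rows, columns=ENSEMBLE_COLUMNS)
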