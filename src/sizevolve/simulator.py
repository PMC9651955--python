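"""Volume-coupled cell-cycle simulator.

Couples network concentration dynamics to an exponentially growing,
symmetrically dividing cell with a two-phase cycle: a size-controlled
phase gated by a decreasing Hill hazard on the G1/S inhibitor (sensed as
quantity I = [I]*V or as concentration [I]) and a timer phase of mean
duration ``timer_fraction * tau`` with uniform multiplicative noise.  Both
cycle structures are supported: the budding-yeast-like default (G1
control, S/G2/M timer) and the fission-yeast-like inversion (G1 timer,
S/G2/M control).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import _kernel
from .network import (KIND_ACTIVATION, KIND_COMPLEX, KIND_REPRESSION,
                      NetworkError, NetworkSpec, ROLE_SWITCH)

STRUCTURE_CONTROL = "control"   # G1 size control + S/G2/M timer
STRUCTURE_POMBE = "pombe"       # G1 timer + S/G2/M size control
SENSING_QUANTITY = "quantity"
SENSING_CONCENTRATION = "concentration"

#: Cycle-table column order of the lineage CSV schema.
CYCLE_COLUMNS = ["cycle_index", "t_birth", "V_birth", "t_G1S", "V_G1S",
                 "t_div", "V_div", "T_G1", "T_SG2M", "T_cycle",
                 "dV_G1", "dV_SG2M", "dV_cycle", "perturbed", "capped"]


class SimulationError(RuntimeError):
    pass


@dataclass
class HazardParams:
    """Decreasing Hill hazard for the size-controlled transition.

    ``h(sensed) = h_max * K_h^n_h / (K_h^n_h + sensed^n_h)`` so that a low
    inhibitor signal means a high chance of progressing.  ``K_h`` is in
    quantity units under quantity sensing and concentration units under
    concentration sensing.
    """

    h_max: float = 20.0
    K_h: float = 0.16
    n_h: float = 4.0


@dataclass
class CycleConfig:
    """Growth, cycle structure, sensing and noise settings (the environment).

    Defaults model a cell doubling every ``tau = ln(2)/0.5 ~ 1.39`` time
    units (one time unit ~ 30 min) whose S/G2/M timer takes 54% of the
    doubling time, with modest uniform timer noise and no growth-rate,
    partition or molecular noise.  The default horizon of 150 time units
    (~108 cycles) is long enough that an unstable lineage reveals itself
    within a single evaluation.  Volume is in units of the typical birth
    size; lineages die below ``V_min`` and are capped (and penalized) at
    ``V_max``.
    """

    growth_rate: float = 0.5
    structure: str = STRUCTURE_CONTROL
    sensing: str = SENSING_QUANTITY
    timer_fraction: float = 0.54
    timer_noise_width: float = 0.1
    growth_cv: float = 0.0
    partition_cv: float = 0.0
    molecular_noise: bool = False
    omega0: float = 1000.0
    hazard: HazardParams = field(default_factory=HazardParams)
    V_min: float = 0.1
    V_max: float = 10.0
    V_init: float = 1.0
    dt: float = 0.01
    T_total: float = 150.0
    warmup_cycles: int = 10

    @property
    def tau(self) -> float:
        """Doubling time ln(2)/lambda (derived, never stored)."""
        return math.log(2.0) / self.growth_rate

    def validate(self) -> "CycleConfig":
        if self.growth_rate <= 0:
            raise ValueError("growth_rate must be > 0")
        if not 0 < self.timer_fraction < 1:
            raise ValueError("timer_fraction must be in (0, 1)")
        if not 0 <= self.timer_noise_width < 1:
            raise ValueError("timer_noise_width must be in [0, 1)")
        if self.structure not in (STRUCTURE_CONTROL, STRUCTURE_POMBE):
            raise ValueError(f"unknown cycle structure {self.structure!r}")
        if self.sensing not in (SENSING_QUANTITY, SENSING_CONCENTRATION):
            raise ValueError(f"unknown sensing mode {self.sensing!r}")
        if not self.V_min < self.V_init < self.V_max:
            raise ValueError("volume bounds must satisfy V_min < V_init < V_max")
        if self.dt <= 0 or self.T_total <= 0:
            raise ValueError("dt and T_total must be > 0")
        if self.hazard.h_max <= 0 or self.hazard.K_h <= 0 or self.hazard.n_h < 1:
            raise ValueError("hazard parameters out of range")
        return self

    def replace(self, **kw) -> "CycleConfig":
        return replace(self, **kw).validate()


@dataclass
class CellState:
    """Instantaneous state of the followed cell."""

    t: float
    V: float
    phase: int                       # switch value: 0 in G1, 1 in S/G2/M
    concentrations: dict[str, float]
    timer_deadline: float | None = None


@dataclass
class LineageRecord:
    """Time-ordered outcome of a single-cell lineage simulation.

    ``cycles`` is the per-cycle table (one row per completed cycle, schema
    ``CYCLE_COLUMNS`` plus per-species concentration snapshots at birth
    and at G1/S); ``trace`` optionally holds the event-level trace
    (t, V, phase, one column per species).
    """

    cycles: pd.DataFrame
    species: list[str]
    died: bool = False
    capped: bool = False
    t_end: float = 0.0
    trace: pd.DataFrame | None = None
    config: CycleConfig | None = None

    @property
    def n_divisions(self) -> int:
        return len(self.cycles)

    def steady_cycles(self, warmup: int | None = None) -> pd.DataFrame:
        """Post-warm-up cycles (initial-condition transients dropped)."""
        if warmup is None:
            warmup = self.config.warmup_cycles if self.config else 10
        return self.cycles.iloc[warmup:]


# ---------------------------------------------------------------------
# Elementary operations (exposed for tests and analysis)
# ---------------------------------------------------------------------

def g1s_hazard(sensed: float, params: HazardParams) -> float:
    """Transition rate (1/time) of the size-controlled transition.

    Strictly decreasing in the sensed inhibitor signal; the per-step
    transition probability over ``dt`` is ``1 - exp(-h*dt)``.
    """
    if sensed < 0:
        raise ValueError(f"sensed signal must be >= 0, got {sensed}")
    kn = params.K_h ** params.n_h
    return params.h_max * kn / (kn + sensed ** params.n_h)


def sample_timer_duration(config: CycleConfig,
                          rng: np.random.Generator) -> float:
    """Draw one timer-phase duration f_T*tau*(1 + U(-w, +w))."""
    w = config.timer_noise_width
    base = config.timer_fraction * config.tau
    if w == 0:
        return base
    return base * (1.0 + rng.uniform(-w, w))


def divide_cell(state: CellState, partition_cv: float,
                rng: np.random.Generator) -> CellState:
    """Divide the cell and return the followed daughter.

    The division fraction f is 1/2, or Normal(0.5, 0.5*partition_cv)
    truncated to +-3 sd under partition noise.  Quantities split in ratio
    f:(1-f), so concentrations are identical before and after division.
    """
    if state.V <= 0:
        raise ValueError("cannot divide a cell with nonpositive volume")
    f = 0.5
    if partition_cv > 0:
        sd = 0.5 * partition_cv
        for _ in range(100):
            f = 0.5 + sd * rng.standard_normal()
            if abs(f - 0.5) < 3 * sd and 0 < f < 1:
                break
    return CellState(t=state.t, V=f * state.V, phase=0,
                     concentrations=dict(state.concentrations),
                     timer_deadline=None)


# ---------------------------------------------------------------------
# Network compilation
# ---------------------------------------------------------------------

@dataclass
class CompiledNetwork:
    """Flat-array form of a network consumed by the numba kernel."""

    names: list[str]
    index: dict[str, int]
    idx_I: int
    x0: np.ndarray
    delta: np.ndarray
    rho0: np.ndarray
    asrc: np.ndarray
    atgt: np.ndarray
    arho: np.ndarray
    aK: np.ndarray
    an: np.ndarray
    rsrc: np.ndarray
    rtgt: np.ndarray
    rK: np.ndarray
    rn: np.ndarray
    cA: np.ndarray
    cB: np.ndarray
    cC: np.ndarray
    ckon: np.ndarray
    ckoff: np.ndarray


def compile_network(network: NetworkSpec) -> CompiledNetwork:
    """Flatten a validated network into kernel arrays.

    Dynamic species are the non-switch species followed by the implicit
    complexes; the switch is encoded as transcription source index -1.
    """
    network.validate()
    registry = network.complex_registry()
    proteins = [s for s in network.species if s.role != ROLE_SWITCH]
    names = [s.id for s in proteins] + list(registry)
    index = {nm: i for i, nm in enumerate(names)}
    sw = network.switch.id
    n = len(names)

    x0 = np.zeros(n)
    delta = np.zeros(n)
    rho0 = np.zeros(n)
    for s in proteins:
        i = index[s.id]
        x0[i] = s.init_conc
        delta[i] = s.delta
        rho0[i] = s.rho0

    def src_index(sid: str) -> int:
        return -1 if sid == sw else index[sid]

    acts = [ix for ix in network.interactions if ix.kind == KIND_ACTIVATION]
    reps = [ix for ix in network.interactions if ix.kind == KIND_REPRESSION]

    ca, cb, cc, kon, koff = [], [], [], [], []
    for cid, ix in registry.items():
        ca.append(index[ix.sources[0]])
        cb.append(index[ix.sources[1]])
        cc.append(index[cid])
        kon.append(ix.k_on)
        koff.append(ix.k_off)
        delta[index[cid]] = ix.delta_complex

    return CompiledNetwork(
        names=names, index=index, idx_I=index[network.inhibitor.id],
        x0=x0, delta=delta, rho0=rho0,
        asrc=np.array([src_index(ix.sources[0]) for ix in acts], dtype=np.int64),
        atgt=np.array([index[ix.target] for ix in acts], dtype=np.int64),
        arho=np.array([ix.rho for ix in acts], dtype=np.float64),
        aK=np.array([ix.K for ix in acts], dtype=np.float64),
        an=np.array([ix.hill_n for ix in acts], dtype=np.float64),
        rsrc=np.array([src_index(ix.sources[0]) for ix in reps], dtype=np.int64),
        rtgt=np.array([index[ix.target] for ix in reps], dtype=np.int64),
        rK=np.array([ix.K for ix in reps], dtype=np.float64),
        rn=np.array([ix.hill_n for ix in reps], dtype=np.float64),
        cA=np.array(ca, dtype=np.int64), cB=np.array(cb, dtype=np.int64),
        cC=np.array(cc, dtype=np.int64),
        ckon=np.array(kon, dtype=np.float64),
        ckoff=np.array(koff, dtype=np.float64),
    )


# ---------------------------------------------------------------------
# Lineage simulation
# ---------------------------------------------------------------------

def _kernel_seed(seed) -> int:
    if isinstance(seed, np.random.Generator):
        return int(seed.integers(2 ** 31 - 1))
    return int(np.random.default_rng(seed).integers(2 ** 31 - 1))


def simulate_lineage(network: NetworkSpec, config: CycleConfig,
                     seed: int | np.random.Generator = 0,
                     record_trace: bool = False, trace_stride: int = 1,
                     control_volume: float | None = None,
                     control_volume_mode: str = "g1s",
                     perturb_cycle: int = -1,
                     perturb_volume: float = -1.0,
                     initial_volume: float | None = None,
                     max_cycles: int | None = None) -> LineageRecord:
    """Simulate a single-cell lineage and return its record.

    Concentrations are integrated by tau-leaping (forward Euler when
    molecular noise is off) jointly with exponential volume growth
    ``dV/dt = lambda*V``; the control phase transitions stochastically at
    the hazard rate evaluated on the configured sensed variable, the timer
    phase at its sampled deadline.  One daughter is followed per division.
    Lineages die below ``V_min`` (death event, simulation ends) and are
    capped and flagged at ``V_max``.

    ``control_volume`` activates the open-loop protocol: in ``"g1s"`` mode
    the sensed variable uses the fixed Vc in place of the actual volume
    (volume bounds are released so the drifting true volume does not kill
    the record); in ``"birth"`` mode the actual volume is reset to Vc at
    each division, which sets the molecular-noise scale of a cell born at
    Vc.  ``perturb_cycle``/``perturb_volume`` force the birth volume of
    one cycle (the perturbation-recovery protocol).
    """
    config.validate()
    compiled = compile_network(network)

    cv_mode = 0
    Vc = 0.0
    V_min, V_max = config.V_min, config.V_max
    if control_volume is not None:
        if control_volume <= 0:
            raise ValueError("control volume must be > 0")
        Vc = float(control_volume)
        if control_volume_mode == "g1s":
            cv_mode = 1
            V_min, V_max = 0.0, np.inf
        elif control_volume_mode == "birth":
            cv_mode = 2
        else:
            raise ValueError(f"unknown control-volume mode {control_volume_mode!r}")

    if max_cycles is None:
        # cycles cannot be shorter than the incompressible timer phase
        shortest = config.timer_fraction * config.tau * (1 - config.timer_noise_width)
        max_cycles = int(config.T_total / max(shortest, 10 * config.dt)) + 8

    out = _kernel.run_lineage_kernel(
        _kernel_seed(seed),
        compiled.x0, compiled.delta, compiled.rho0,
        compiled.asrc, compiled.atgt, compiled.arho, compiled.aK, compiled.an,
        compiled.rsrc, compiled.rtgt, compiled.rK, compiled.rn,
        compiled.cA, compiled.cB, compiled.cC, compiled.ckon, compiled.ckoff,
        compiled.idx_I,
        config.growth_rate, config.dt, config.T_total,
        float(initial_volume if initial_volume is not None else config.V_init),
        0 if config.structure == STRUCTURE_CONTROL else 1,
        0 if config.sensing == SENSING_QUANTITY else 1,
        config.timer_fraction, config.timer_noise_width,
        config.growth_cv, config.partition_cv,
        1 if config.molecular_noise else 0, config.omega0,
        config.hazard.h_max, config.hazard.K_h, config.hazard.n_h,
        V_min, V_max,
        cv_mode, Vc,
        perturb_cycle, perturb_volume,
        max_cycles, trace_stride if record_trace else 0,
    )
    (status, capped, n_cyc, t_end,
     t_birth, v_birth, t_g1s, v_g1s, t_div, v_div,
     lam_used, perturbed, cyc_capped, conc_birth, conc_g1s,
     n_trace, tr_t, tr_v, tr_sw, tr_x) = out

    if status == _kernel.STATUS_NONFINITE:
        raise SimulationError(f"non-finite state at t={t_end:.3f}")

    k = n_cyc
    cycles = pd.DataFrame({
        "cycle_index": np.arange(k),
        "t_birth": t_birth[:k], "V_birth": v_birth[:k],
        "t_G1S": t_g1s[:k], "V_G1S": v_g1s[:k],
        "t_div": t_div[:k], "V_div": v_div[:k],
    })
    cycles["T_G1"] = cycles["t_G1S"] - cycles["t_birth"]
    cycles["T_SG2M"] = cycles["t_div"] - cycles["t_G1S"]
    cycles["T_cycle"] = cycles["t_div"] - cycles["t_birth"]
    cycles["dV_G1"] = cycles["V_G1S"] - cycles["V_birth"]
    cycles["dV_SG2M"] = cycles["V_div"] - cycles["V_G1S"]
    cycles["dV_cycle"] = cycles["V_div"] - cycles["V_birth"]
    cycles["perturbed"] = perturbed[:k].astype(bool)
    cycles["capped"] = cyc_capped[:k].astype(bool)
    cycles["growth_rate"] = lam_used[:k]
    for i, nm in enumerate(compiled.names):
        cycles[f"conc_birth_{nm}"] = conc_birth[:k, i]
        cycles[f"conc_G1S_{nm}"] = conc_g1s[:k, i]

    trace = None
    if record_trace:
        trace = pd.DataFrame({"t": tr_t[:n_trace], "V": tr_v[:n_trace],
                              "phase": tr_sw[:n_trace]})
        for i, nm in enumerate(compiled.names):
            trace[nm] = tr_x[:n_trace, i]

    return LineageRecord(cycles=cycles, species=compiled.names,
                         died=(status == _kernel.STATUS_DIED),
                         capped=bool(capped), t_end=float(t_end),
                         trace=trace, config=config)


def apply_size_perturbation(network: NetworkSpec, config: CycleConfig,
                            direction: int, magnitude: float = 0.5,
                            seed: int | np.random.Generator = 0,
                            estimate_cycles: int = 30) -> LineageRecord:
    """Kick one birth volume away from steady state and record the return.

    The lineage is first simulated to estimate the steady-state mean birth
    volume; the continuation is then re-simulated with one division ratio
    altered so the kicked cycle is born at ``(1 +- magnitude)`` times that
    mean, which propagates to the next G1/S volume.  The kicked cycle is
    marked ``perturbed`` in the record.
    """
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 or -1")
    factor = 1.0 + direction * magnitude
    if factor <= 0:
        raise ValueError("perturbation would give a nonpositive volume")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    probe_seed = int(rng.integers(2 ** 31 - 1))
    # the probe shares the kernel seed with the perturbed run, so the
    # pre-kick trajectory is identical and the kick is exactly relative
    # to the run's own steady state
    probe = simulate_lineage(network, config, seed=probe_seed)
    pert_cycle = config.warmup_cycles + estimate_cycles
    window = probe.cycles["V_birth"].to_numpy()[config.warmup_cycles:pert_cycle]
    if len(window) < 10:
        raise SimulationError("need >= 10 steady-state cycles to set the kick")
    target = factor * float(window.mean())
    return simulate_lineage(network, config, seed=probe_seed,
                            perturb_cycle=pert_cycle, perturb_volume=target)
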