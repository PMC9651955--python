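"""Diagnostics that classify size-control mechanisms.

Added-volume slope fits (sizer = -1, adder = 0, timer = +1), birth-size
CV, open-loop control-volume period curves and their analytic archetype
references, perturbation recovery times, heavy-tail (criticality)
statistics of cycle durations, G1 attractor curves, and burst statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import NetworkSpec
from .simulator import (CycleConfig, LineageRecord, SENSING_QUANTITY,
                        compile_network, simulate_lineage)


class AnalysisError(ValueError):
    pass


PHASES = {"G1": ("dV_G1", "V_birth"), "SG2M": ("dV_SG2M", "V_G1S"),
          "cycle": ("dV_cycle", "V_birth")}


@dataclass
class SlopeFit:
    """OLS fit of added volume against phase-entry volume."""

    phase: str
    slope: float
    intercept: float
    rvalue: float
    stderr: float
    n: int
    split: bool = False
    breakpoint: float | None = None
    slope_small: float | None = None
    slope_large: float | None = None


def _ols(x: np.ndarray, y: np.ndarray):
    if len(x) < 2 or np.ptp(x) == 0:
        raise AnalysisError("degenerate regressor: no variation in entry volume")
    return stats.linregress(x, y)


def fit_phase_slopes(record: LineageRecord, phase: str = "cycle",
                     split: bool = False,
                     warmup: int | None = None) -> SlopeFit:
    """Fit ΔV of a cycle phase against the volume entering that phase.

    Entry volume is birth for G1 and the whole cycle, and the G1/S volume
    for S/G2/M.  ``split`` additionally fits two segments about the
    median entry volume (small/large cells can control size differently).
    """
    if phase not in PHASES:
        raise AnalysisError(f"unknown phase {phase!r}")
    dv_col, v_col = PHASES[phase]
    cyc = record.steady_cycles(warmup)
    if len(cyc) < 10:
        raise AnalysisError(f"need >= 10 post-warm-up cycles, got {len(cyc)}")
    x = cyc[v_col].to_numpy()
    y = cyc[dv_col].to_numpy()
    fit = _ols(x, y)
    res = SlopeFit(phase=phase, slope=fit.slope, intercept=fit.intercept,
                   rvalue=fit.rvalue, stderr=fit.stderr, n=len(x))
    if split:
        bp = float(np.median(x))
        lo, hi = x <= bp, x > bp
        if lo.sum() >= 3 and hi.sum() >= 3:
            res.split = True
            res.breakpoint = bp
            res.slope_small = _ols(x[lo], y[lo]).slope
            res.slope_large = _ols(x[hi], y[hi]).slope
    return res


def birth_cv(record: LineageRecord, warmup: int | None = None) -> float:
    """CV (sample std with n-1 denominator, over mean) of birth volumes."""
    v = record.steady_cycles(warmup)["V_birth"].to_numpy()
    if len(v) < 10:
        raise AnalysisError(f"need >= 10 post-warm-up cycles, got {len(v)}")
    return float(np.std(v, ddof=1) / np.mean(v))


def correlate_event_quantities(record: LineageRecord, x: str, y: str,
                               warmup: int | None = None) -> dict:
    """Least-squares line and Pearson correlation of two per-cycle columns.

    Columns are any of the cycle table's, e.g. ``conc_G1S_I`` vs
    ``V_G1S``; a constant y gives slope 0 with correlation flagged NaN.
    """
    cyc = record.steady_cycles(warmup)
    if len(cyc) < 10:
        raise AnalysisError(f"need >= 10 cycles, got {len(cyc)}")
    for col in (x, y):
        if col not in cyc.columns:
            raise AnalysisError(f"column {col!r} not recorded")
    xv, yv = cyc[x].to_numpy(), cyc[y].to_numpy()
    if np.ptp(xv) == 0:
        raise AnalysisError(f"degenerate regressor {x!r}")
    if np.ptp(yv) == 0:
        return {"slope": 0.0, "intercept": float(yv[0]), "r": float("nan"),
                "degenerate": True, "n": len(xv)}
    fit = stats.linregress(xv, yv)
    return {"slope": float(fit.slope), "intercept": float(fit.intercept),
            "r": float(fit.rvalue), "degenerate": False, "n": len(xv)}


# ---------------------------------------------------------------------
# Control-volume period curves
# ---------------------------------------------------------------------

@dataclass
class PeriodCurve:
    """Mean cycle period vs control volume: the mechanism fingerprint."""

    Vc: np.ndarray
    period: np.ndarray          # mean T_cycle / tau per grid point
    dispersion: np.ndarray      # std of T_cycle / tau
    n_cycles: np.ndarray
    mode: str                   # "g1s" (sense at G1/S) or "birth"
    viable: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"Vc": self.Vc, "period": self.period,
                             "dispersion": self.dispersion,
                             "n_cycles": self.n_cycles, "viable": self.viable})


def period_vs_control_volume(network: NetworkSpec, config: CycleConfig,
                             Vc_grid: np.ndarray, mode: str = "g1s",
                             cycles_per_point: int = 50,
                             discard: int = 5,
                             seed: int = 0) -> PeriodCurve:
    """Open the size-feedback loop and measure the induced period T(Vc).

    In ``"g1s"`` mode the sensed variable uses the fixed Vc instead of
    the real (still growing and dividing) volume; in ``"birth"`` mode the
    volume is reset to Vc at each division so Vc sets the molecular-noise
    scale.  Non-viable grid points (no ``cycles_per_point`` transitions
    within the time cutoff) are flagged, not raised.
    """
    Vc_grid = np.asarray(Vc_grid, dtype=float)
    if np.any(Vc_grid <= 0) or np.any(np.diff(Vc_grid) <= 0):
        raise AnalysisError("Vc grid must be positive and strictly increasing")
    rng = np.random.default_rng(seed)
    tau = config.tau
    need = cycles_per_point + discard
    period = np.full(len(Vc_grid), np.nan)
    disp = np.full(len(Vc_grid), np.nan)
    counts = np.zeros(len(Vc_grid), dtype=int)
    viable = np.zeros(len(Vc_grid), dtype=bool)
    # generous cutoff: ten doubling times per requested cycle
    budget = config.replace(T_total=need * tau * 10.0)
    for i, vc in enumerate(Vc_grid):
        rec = simulate_lineage(network, budget, seed=rng,
                               control_volume=float(vc),
                               control_volume_mode=mode)
        T = rec.cycles["T_cycle"].to_numpy()[discard:]
        counts[i] = len(T)
        if len(T) >= cycles_per_point:
            viable[i] = True
            period[i] = float(np.mean(T) / tau)
            disp[i] = float(np.std(T, ddof=1) / tau)
    return PeriodCurve(Vc=Vc_grid, period=period, dispersion=disp,
                       n_cycles=counts, mode=mode, viable=viable)


def archetype_period(archetype: str, Vc: float, v_g1s_eq: float,
                     timer_fraction: float) -> float:
    """Analytic reference T(Vc)/tau for the timer/adder/sizer archetypes.

    All three curves pass through (v_g1s_eq, 1): at the equilibrium
    volume the induced period equals the doubling time.  The sizer grows
    to the fixed volume 2*v_g1s_eq believing it starts at Vc, the adder
    believes it adds v_g1s_eq, and the timer always takes tau.  Periods
    are floored at the incompressible timer fraction, which is what
    prevents a perfect sizer at large volumes.
    """
    if Vc <= 0:
        raise AnalysisError(f"control volume must be > 0, got {Vc}")
    r = Vc / v_g1s_eq
    if archetype == "timer":
        t = 1.0
    elif archetype == "sizer":
        t = 1.0 - math.log2(r)
    elif archetype == "adder":
        t = math.log2(1.0 + 1.0 / r)
    else:
        raise AnalysisError(f"unknown archetype {archetype!r}")
    return max(t, timer_fraction)


# ---------------------------------------------------------------------
# Perturbation recovery
# ---------------------------------------------------------------------

def recovery_generations(record: LineageRecord, band: float = 0.1,
                         min_pre_cycles: int = 10) -> int | None:
    """Generations to return to the steady-state G1/S volume band.

    The band center is the mean V_G1S over the cycles before the marked
    perturbation; recovery is the 1-based index of the first post-kick
    cycle whose V_G1S is inside ``center*(1 ± band)`` and stays there for
    2 consecutive cycles.  Returns 0 for an unperturbed record and None
    (censored) when the lineage never re-enters within the record.
    """
    cyc = record.cycles
    marks = np.flatnonzero(cyc["perturbed"].to_numpy())
    if len(marks) == 0:
        return 0
    k = int(marks[0])
    pre = cyc["V_G1S"].to_numpy()[max(0, k - 5 * min_pre_cycles):k]
    if len(pre) < min_pre_cycles:
        raise AnalysisError("need >= 10 pre-perturbation cycles")
    center = float(np.mean(pre))
    post = cyc["V_G1S"].to_numpy()[k:]
    inside = np.abs(post / center - 1.0) <= band
    for g in range(len(inside) - 1):
        if inside[g] and inside[g + 1]:
            return g + 1
    return None


# ---------------------------------------------------------------------
# Criticality statistics
# ---------------------------------------------------------------------

def ccdf_tail_fit(durations: np.ndarray, threshold_quantile: float = 0.9,
                  sensitivity: tuple[float, float] = (0.85, 0.95)) -> dict:
    """Fit the log-log tail of the CCDF of cycle durations.

    The empirical complementary CDF is fit by least squares above the
    threshold quantile.  The exponent uses the negative-slope convention
    (a Pareto(alpha) sample gives ~ -alpha).  A drift of the fitted
    exponent across the sensitivity thresholds flags curvature, i.e. a
    distribution whose tail is not power-law.
    """
    d = np.sort(np.asarray(durations, dtype=float))
    if len(d) < 500:
        raise AnalysisError(f"need >= 500 durations, got {len(d)}")
    if np.ptp(d) == 0:
        raise AnalysisError("degenerate (constant) duration distribution")

    def _fit(q: float) -> float:
        thr = np.quantile(d, q)
        tail = d[d > thr]
        # CCDF at the sorted tail points
        ccdf = 1.0 - (np.searchsorted(d, tail, side="right") / len(d))
        keep = ccdf > 0
        x, y = np.log(tail[keep]), np.log(ccdf[keep])
        if len(x) < 10 or np.ptp(x) == 0:
            raise AnalysisError("tail too short for a fit")
        return float(stats.linregress(x, y).slope)

    expo = _fit(threshold_quantile)
    lo, hi = (_fit(q) for q in sensitivity)
    drift = abs(hi - lo)
    return {"exponent": expo, "threshold_quantile": threshold_quantile,
            "threshold": float(np.quantile(d, threshold_quantile)),
            "exponent_lo": lo, "exponent_hi": hi,
            "non_power_law": bool(drift > 1.0), "n": len(d)}


def tail_mass_beyond(durations: np.ndarray, cutoff: float) -> float:
    """Fraction of cycle durations exceeding ``cutoff`` (e.g. tau)."""
    d = np.asarray(durations, dtype=float)
    return float(np.mean(d > cutoff))


# ---------------------------------------------------------------------
# G1 attractor and bursts
# ---------------------------------------------------------------------

def g1_attractor_curve(network: NetworkSpec, activator: str,
                       A_grid: np.ndarray, config: CycleConfig,
                       volume: float = 1.0, t_max: float = 200.0,
                       tol: float = 1e-10) -> pd.DataFrame:
    """Deterministic G1-branch attractor of [I] as a function of clamped [A].

    For each clamped activator concentration the switch is held at 0 and
    the remaining deterministic dynamics are integrated to their fixed
    point.  The returned frame reports the attractor [I] per grid point,
    the concentration that triggers the G1/S transition (the hazard's
    half-max, K_h/V under quantity sensing), and whether the attractor
    exceeds it — the bifurcation between the cycling and the stuck-in-G1
    regimes.  Points that fail to converge are flagged, not raised.
    """
    compiled = compile_network(network)
    if activator not in compiled.index:
        raise AnalysisError(f"species {activator!r} not in the network")
    ia = compiled.index[activator]
    lam = config.growth_rate
    dt = config.dt
    if config.sensing == SENSING_QUANTITY:
        trigger = config.hazard.K_h / volume
    else:
        trigger = config.hazard.K_h

    rows = []
    for a in np.asarray(A_grid, dtype=float):
        x = compiled.x0.copy()
        x[ia] = a
        converged = False
        for _ in range(int(t_max / dt)):
            prod = compiled.rho0.copy()
            for j in range(len(compiled.asrc)):
                s = compiled.asrc[j]
                h = 0.0 if s == -1 else (
                    x[s] ** compiled.an[j]
                    / (compiled.aK[j] ** compiled.an[j] + x[s] ** compiled.an[j]))
                prod[compiled.atgt[j]] += compiled.arho[j] * h
            for j in range(len(compiled.rsrc)):
                s = compiled.rsrc[j]
                h = 1.0 if s == -1 else (
                    compiled.rK[j] ** compiled.rn[j]
                    / (compiled.rK[j] ** compiled.rn[j] + x[s] ** compiled.rn[j]))
                prod[compiled.rtgt[j]] *= h
            dx = (prod - compiled.delta * x - lam * x) * dt
            for j in range(len(compiled.cA)):
                flux = (compiled.ckon[j] * x[compiled.cA[j]] * x[compiled.cB[j]]
                        - compiled.ckoff[j] * x[compiled.cC[j]]) * dt
                dx[compiled.cA[j]] -= flux
                dx[compiled.cB[j]] -= flux
                dx[compiled.cC[j]] += flux
            x = np.maximum(x + dx, 0.0)
            x[ia] = a
            if np.max(np.abs(dx)) < tol:
                converged = True
                break
        rows.append({"A": a, "I_attractor": float(x[compiled.idx_I]),
                     "trigger_conc": trigger,
                     "above_trigger": bool(x[compiled.idx_I] > trigger),
                     "converged": converged})
    return pd.DataFrame(rows)


def attractor_crossing(curve: pd.DataFrame) -> tuple[float, float] | None:
    """Bracket [A_lo, A_hi] where the attractor first exceeds the trigger."""
    above = curve["above_trigger"].to_numpy()
    idx = np.flatnonzero(above)
    if len(idx) == 0 or idx[0] == 0:
        return None
    i = int(idx[0])
    return (float(curve["A"].iloc[i - 1]), float(curve["A"].iloc[i]))


def burst_statistics(record: LineageRecord, species: str,
                     floor: float = 1e-3) -> pd.DataFrame:
    """Per-cycle burst duration and G1 amplitude of an activator species.

    Duration is the total time within a cycle during which the species'
    concentration exceeds ``floor`` (a strictly positive floor stands in
    for "above zero", which is measure-zero under continuous noise);
    amplitude is its mean concentration over that cycle's G1 phase.  Each
    row is tagged with the cycle's birth volume.
    """
    if record.trace is None:
        raise AnalysisError("record has no event-level trace")
    if species not in record.trace.columns:
        raise AnalysisError(f"species {species!r} not in the trace")
    tr = record.trace
    dt_tr = float(np.median(np.diff(tr["t"].to_numpy()))) if len(tr) > 1 else 0.0
    rows = []
    for _, cyc in record.cycles.iterrows():
        sel = (tr["t"] >= cyc["t_birth"]) & (tr["t"] < cyc["t_div"])
        sub = tr[sel]
        if len(sub) == 0:
            continue
        a = sub[species].to_numpy()
        duration = float(np.sum(a > floor) * dt_tr)
        g1 = sub[sub["phase"] == 0] if record.config is None or \
            record.config.structure == "control" else sub[sub["phase"] == 1]
        amplitude = float(g1[species].mean()) if len(g1) else float("nan")
        rows.append({"cycle_index": int(cyc["cycle_index"]),
                     "burst_duration": duration, "burst_amplitude": amplitude,
                     "V_birth": float(cyc["V_birth"])})
    return pd.DataFrame(rows)


def predicted_added_volume(period_norm: float, V: float) -> float:
    """ΔV implied by a normalized period at volume V under exponential growth.

    A cell of volume V cycling with period T grows by V*(2**(T/tau) - 1);
    this maps a T(Vc) curve to a predicted added-volume curve.
    """
    return V * (2.0 ** period_norm - 1.0)
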