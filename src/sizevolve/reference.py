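"""Reference network topologies and ideal-rule oracle lineages.

Builders construct the platform's reference network topologies
programmatically (the seed relaxation oscillator, the mixed-feedback-loop
size sensor, and the fluctuation-sensing network), with parameters
produced by :func:`calibrate_homeostasis`.  The
ideal-rule lineages realize the sizer / adder / timer archetypes exactly
and serve as oracles for every slope- and recovery-based diagnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import (KIND_ACTIVATION, KIND_COMPLEX, KIND_REPRESSION,
                      InteractionSpec, NetworkSpec, ROLE_INHIBITOR,
                      ROLE_PROTEIN, ROLE_SWITCH, SpeciesSpec)
from .simulator import (CycleConfig, HazardParams, LineageRecord,
                        SENSING_CONCENTRATION, simulate_lineage)


# ---------------------------------------------------------------------
# Topology builders
# ---------------------------------------------------------------------

def seed_network() -> NetworkSpec:
    """The seed relaxation oscillator: Switch -> I activation only.

    The inhibitor I gates the G1/S transition through its quantity (the
    gating itself lives in the simulator and cannot be mutated); the
    S/G2/M switch activates I production so its concentration is reset to
    a high level before the next generation.  This network performs no
    size control: size deviations are amplified every generation.
    """
    return NetworkSpec(
        species=[
            SpeciesSpec("I", ROLE_INHIBITOR, delta=2.0, rho0=0.0,
                        init_conc=0.8),
            SpeciesSpec("Switch", ROLE_SWITCH),
        ],
        interactions=[
            InteractionSpec(KIND_ACTIVATION, ("Switch",), "I",
                            rho=2.4, K=1.0, hill_n=1.0),
        ],
    ).validate()


def mixed_feedback_network(a2: bool = False) -> NetworkSpec:
    """Mixed-feedback-loop size controller (evolved topology, class A).

    One gene R is added to the seed network and is both repressed and
    titrated by I: R is produced only in the narrow low-[I] window around
    the G1/S transition, so its level remembers the volume at G1/S; the
    I+R complex then titrates I in proportion to that volume, making the
    inhibitor's decay size-dependent and closing the homeostatic loop.
    With ``a2`` two further interactions are added (the switch shuts down
    R production in S/G2/M and R represses I synthesis), the richer
    variant of the same mechanism.

    Parameters are the package's own calibration (see
    :func:`calibrate_homeostasis`), not values from elsewhere.
    """
    net = NetworkSpec(
        species=[
            SpeciesSpec("I", ROLE_INHIBITOR, delta=0.432, rho0=0.0,
                        init_conc=0.8),
            SpeciesSpec("R", ROLE_PROTEIN, delta=0.546, rho0=2.47,
                        init_conc=0.1),
            SpeciesSpec("Switch", ROLE_SWITCH),
        ],
        interactions=[
            InteractionSpec(KIND_ACTIVATION, ("Switch",), "I",
                            rho=2.88, K=0.47, hill_n=1.0),
            InteractionSpec(KIND_REPRESSION, ("I",), "R",
                            K=0.573, hill_n=4.0),
            InteractionSpec(KIND_COMPLEX, ("I", "R"), "R",
                            k_on=7.44, k_off=0.176, delta_complex=0.392),
        ],
    )
    if a2:
        # the richer variant carries its own calibration
        i, r = net.get_species("I"), net.get_species("R")
        i.delta = 0.861
        r.delta = 1.964
        r.rho0 = 8.69
        act, rep, cpx = net.interactions
        act.rho, act.K = 8.18, 1.48
        rep.K = 1.62
        cpx.k_on, cpx.k_off, cpx.delta_complex = 8.91, 0.159, 0.978
        net.interactions.append(InteractionSpec(
            KIND_REPRESSION, ("Switch",), "R", K=1.32, hill_n=1.0))
        net.interactions.append(InteractionSpec(
            KIND_REPRESSION, ("R",), "I", K=0.521, hill_n=2.0))
    return net.validate()


def fluctuation_network() -> NetworkSpec:
    """Concentration-sensing network with a self-activating burst gene (B).

    A self-activates with a steep Hill function and activates I production
    equally steeply; at small volumes Poissonian concentration
    fluctuations push [A] over its activation threshold, triggering a
    burst of inhibitor and a much longer G1.  Meant to be run with
    concentration sensing and molecular noise on (see
    :func:`fluctuation_config`).
    """
    return NetworkSpec(
        species=[
            SpeciesSpec("I", ROLE_INHIBITOR, delta=2.0, rho0=0.0,
                        init_conc=0.8),
            SpeciesSpec("A", ROLE_PROTEIN, delta=2.0, rho0=0.01,
                        init_conc=0.0),
            SpeciesSpec("Switch", ROLE_SWITCH),
        ],
        interactions=[
            InteractionSpec(KIND_ACTIVATION, ("Switch",), "I",
                            rho=2.9, K=1.0, hill_n=1.0),
            InteractionSpec(KIND_ACTIVATION, ("A",), "A",
                            rho=0.04, K=0.02, hill_n=8.0),
            InteractionSpec(KIND_ACTIVATION, ("A",), "I",
                            rho=20.0, K=0.015, hill_n=8.0),
        ],
    ).validate()


def fluctuation_config(**overrides) -> CycleConfig:
    """Cycle configuration preset for the fluctuation-sensing model.

    Concentration sensing with molecular noise on; the death bound is
    lowered because statistical size control lets cells shrink well below
    the typical birth size before a burst rescues the lineage.
    """
    kw = dict(sensing=SENSING_CONCENTRATION, molecular_noise=True,
              V_min=0.02,
              hazard=HazardParams(h_max=20.0, K_h=0.35, n_h=4.0))
    kw.update(overrides)
    return CycleConfig(**kw).validate()


# ---------------------------------------------------------------------
# Ideal-rule oracle lineages
# ---------------------------------------------------------------------

def ideal_rule_lineage(rule: str, n_cycles: int, noise: float = 0.05,
                       config: CycleConfig | None = None,
                       seed: int | np.random.Generator = 0,
                       perturb_cycle: int = -1,
                       perturb_volume: float = -1.0) -> LineageRecord:
    """Lineage obeying an archetypal size-control rule exactly.

    Bypasses networks entirely: the sizer divides at a fixed size, the
    adder divides after adding a fixed volume, the timer divides after
    exactly one doubling time.  Cell-to-cell variability is injected as
    multiplicative lognormal jitter of the division fraction at the
    stated CV, which keeps each archetype's return map — and hence its
    defining added-volume slope — exact while giving birth sizes a
    realistic spread.  The G1/S point is placed so S/G2/M is a timer of
    the configured fraction of the doubling time.  Records share the
    simulator's schema.
    """
    if n_cycles < 1:
        raise ValueError("need at least one cycle")
    if rule not in ("sizer", "adder", "timer"):
        raise ValueError(f"unknown rule {rule!r}")
    config = (config or CycleConfig()).validate()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    tau = config.tau
    f_T = config.timer_fraction
    V_STAR = 2.0     # sizer division size
    DV_STAR = 1.0    # adder increment

    rows = np.zeros((n_cycles, 7))
    t = 0.0
    V = 1.0
    sig = float(noise)
    for k in range(n_cycles):
        if k == perturb_cycle and perturb_volume > 0:
            V = perturb_volume
        Vb = V
        if rule == "sizer":
            Vd = V_STAR
        elif rule == "adder":
            Vd = Vb + DV_STAR
        else:
            Vd = 2.0 * Vb
        T = tau * math.log2(Vd / Vb) if Vd > Vb else 0.0
        T_sg2m = min(f_T * tau, T)
        Vg = Vd * 2.0 ** (-T_sg2m / tau)
        rows[k] = (t, Vb, t + T - T_sg2m, Vg, t + T, Vd,
                   1.0 if k == perturb_cycle else 0.0)
        t += T
        f = 0.5
        if sig > 0:
            f = 0.5 * math.exp(sig * rng.standard_normal() - 0.5 * sig * sig)
            f = min(max(f, 0.05), 0.95)
        V = f * Vd

    cycles = pd.DataFrame(rows, columns=["t_birth", "V_birth", "t_G1S",
                                         "V_G1S", "t_div", "V_div",
                                         "perturbed"])
    cycles.insert(0, "cycle_index", np.arange(n_cycles))
    cycles["T_G1"] = cycles["t_G1S"] - cycles["t_birth"]
    cycles["T_SG2M"] = cycles["t_div"] - cycles["t_G1S"]
    cycles["T_cycle"] = cycles["t_div"] - cycles["t_birth"]
    cycles["dV_G1"] = cycles["V_G1S"] - cycles["V_birth"]
    cycles["dV_SG2M"] = cycles["V_div"] - cycles["V_G1S"]
    cycles["dV_cycle"] = cycles["V_div"] - cycles["V_birth"]
    cycles["perturbed"] = cycles["perturbed"].astype(bool)
    cycles["capped"] = False
    cycles["growth_rate"] = config.growth_rate
    return LineageRecord(cycles=cycles, species=[], died=False, capped=False,
                         t_end=t, trace=None, config=config)


# ---------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------

class CalibrationError(RuntimeError):
    def __init__(self, message: str, best: "CalibrationResult | None" = None):
        super().__init__(message)
        self.best = best


@dataclass
class CalibrationResult:
    network: NetworkSpec
    ndiv: int
    cv_birth: float
    penalized: bool


def _param_refs(network: NetworkSpec):
    refs = []
    for s in network.species:
        if s.role == ROLE_SWITCH:
            continue
        if s.delta > 0:
            refs.append(("species", s.id, "delta"))
        if s.rho0 > 0:
            refs.append(("species", s.id, "rho0"))
    for xi, ix in enumerate(network.interactions):
        if not ix.mutable:
            continue
        for name in ix.params():
            if name == "hill_n":
                continue
            refs.append(("interaction", xi, name))
    return refs


def _get(net: NetworkSpec, ref):
    kind, key, name = ref
    obj = net.get_species(key) if kind == "species" else net.interactions[key]
    return getattr(obj, name)


def _set(net: NetworkSpec, ref, value: float):
    kind, key, name = ref
    obj = net.get_species(key) if kind == "species" else net.interactions[key]
    setattr(obj, name, value)


def _score(network: NetworkSpec, config: CycleConfig, eval_seed: int):
    rec = simulate_lineage(network, config, seed=eval_seed)
    penalized = rec.died or rec.capped
    cv = math.inf
    if not penalized:
        steady = rec.steady_cycles()
        if len(steady) >= 10:
            v = steady["V_birth"].to_numpy()
            cv = float(np.std(v, ddof=1) / np.mean(v))
        else:
            penalized = True
    return CalibrationResult(network=network, ndiv=rec.n_divisions,
                             cv_birth=cv, penalized=penalized)


def _better(a: CalibrationResult, b: CalibrationResult) -> bool:
    """a better than b: viability first, then NDiv, then CVBirth."""
    ka = (not a.penalized, a.ndiv, -a.cv_birth if np.isfinite(a.cv_birth) else -1e9)
    kb = (not b.penalized, b.ndiv, -b.cv_birth if np.isfinite(b.cv_birth) else -1e9)
    return ka > kb


def calibrate_homeostasis(network: NetworkSpec, config: CycleConfig,
                          n_random: int = 2000, n_descent: int = 200,
                          spread: float = 1.5,
                          seed: int = 0) -> CalibrationResult:
    """Search kinetic parameters for a viable, low-CV homeostatic lineage.

    The topology is fixed.  A log-normal random search around the current
    parameterization (multiplicative spread ``exp(±spread)``) maximizes
    viability then NDiv then minimizes CVBirth; coordinate descent with
    multiplicative steps then polishes the best candidate.  Deterministic
    under ``seed``.  Raises :class:`CalibrationError` (carrying the best
    attempt) if no non-penalized parameterization is found — which is the
    expected outcome for topologies that cannot control size, such as the
    seed network.
    """
    network = network.copy().validate()
    rng = np.random.default_rng(seed)
    eval_seed = int(rng.integers(2 ** 31 - 1))
    refs = _param_refs(network)
    base = [_get(network, r) for r in refs]
    best = _score(network.copy(), config, eval_seed)
    for _ in range(n_random):
        cand = network.copy()
        for r, b in zip(refs, base):
            _set(cand, r, b * math.exp(rng.uniform(-spread, spread)))
        res = _score(cand, config, eval_seed)
        if _better(res, best):
            best = res
    step = 0.2
    since_improvement = 0
    for it in range(n_descent):
        r = refs[it % len(refs)]
        improved = False
        for sgn in (+1.0, -1.0):
            cand = best.network.copy()
            _set(cand, r, _get(cand, r) * math.exp(sgn * step))
            res = _score(cand, config, eval_seed)
            if _better(res, best):
                best = res
                improved = True
        since_improvement = 0 if improved else since_improvement + 1
        if since_improvement >= 2 * len(refs):
            step *= 0.5
            since_improvement = 0
            if step < 0.02:
                break
    if best.penalized:
        raise CalibrationError(
            f"no viable parameterization found (best: NDiv={best.ndiv}, "
            f"died/capped lineage)", best=best)
    return best
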