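"""Mutation + Pareto selection over network populations.

Populations of networks are evaluated on lineage-derived fitnesses
(number of divisions NDiv to maximize, birth-size CV to minimize, or the
alternative target-size / added-volume-slope objectives), Pareto ranked,
and the surviving half is duplicated and mutated.  Mutation rates follow
a numerical Drake's rule: probabilities are normalized so each network
receives on average one mutation per epoch regardless of its size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import AnalysisError, birth_cv, fit_phase_slopes
from .network import (KIND_ACTIVATION, KIND_COMPLEX, KIND_REPRESSION,
                      InteractionSpec, NetworkSpec, PARAM_BOUNDS, ROLE_PROTEIN,
                      ROLE_SWITCH, SpeciesSpec, serialize_network)
from .simulator import CycleConfig, LineageRecord, SimulationError, simulate_lineage

#: Relative mutation-move weights, most to least probable.
DEFAULT_MOVE_WEIGHTS = {"parameter": 0.8, "removal": 0.15, "addition": 0.05}

#: CVBirth assigned to dead / volume-capped / degenerate lineages,
#: far above any value a viable lineage produces.
PENALTY_CV = 10.0

LOGNORMAL_STEP_SIGMA = 0.3
SHARE_RADIUS = 0.1


class EvolutionError(RuntimeError):
    pass


@dataclass
class FitnessVector:
    """Selection surface of one individual."""

    ndiv: int = 0
    cv_birth: float = PENALTY_CV
    died: bool = False
    capped: bool = False
    extras: dict = field(default_factory=dict)

    def objective(self, name: str) -> float:
        """Value of a named objective, oriented so larger is better."""
        if name == "ndiv":
            return float(self.ndiv)
        if name == "cv_birth":
            return -self.cv_birth
        if name in self.extras:
            return -float(self.extras[name])
        raise EvolutionError(f"objective {name!r} not evaluated")


@dataclass
class Individual:
    network: NetworkSpec
    fitness: FitnessVector | None = None
    uid: int = -1


@dataclass
class MutationMove:
    kind: str
    target: str
    detail: str = ""


# ---------------------------------------------------------------------
# Drake-rule mutation schedule
# ---------------------------------------------------------------------

@dataclass
class MoveSlot:
    kind: str          # parameter | removal | add-interaction | add-species
    index: int         # interaction index, species index, or -1
    name: str = ""     # parameter name for parameter moves
    prob: float = 0.0


def _parameter_slots(network: NetworkSpec) -> list[MoveSlot]:
    slots = []
    for si, s in enumerate(network.species):
        if s.role == ROLE_SWITCH:
            continue
        if s.delta > 0:
            slots.append(MoveSlot("parameter", -1 - si, "delta"))
        if s.rho0 > 0:
            slots.append(MoveSlot("parameter", -1 - si, "rho0"))
    for xi, ix in enumerate(network.interactions):
        if not ix.mutable:
            continue
        for name in ix.params():
            slots.append(MoveSlot("parameter", xi, name))
    return slots


def drake_rate_schedule(network: NetworkSpec,
                        base_weights: dict | None = None) -> list[MoveSlot]:
    """Per-element move probabilities normalized to one move per epoch.

    Each mutable element (every numeric parameter, every removable
    interaction, and the two addition slots) gets a probability so that
    the expected number of applied moves is exactly 1, with the weight
    mass split parameter-change > removal > addition and uniformly within
    each kind.  Kinds with no candidates donate their mass to the rest.
    """
    w = dict(DEFAULT_MOVE_WEIGHTS if base_weights is None else base_weights)
    params = _parameter_slots(network)
    removables = [MoveSlot("removal", xi) for xi, ix in
                  enumerate(network.interactions) if ix.mutable]
    additions = [MoveSlot("add-interaction", -1), MoveSlot("add-species", -1)]
    groups = [("parameter", params), ("removal", removables),
              ("addition", additions)]
    active = [(k, slots) for k, slots in groups if slots and w.get(k, 0) > 0]
    if not active:
        raise EvolutionError("network has no mutable elements")
    total_w = sum(w[k] for k, _ in active)
    out = []
    for k, slots in active:
        share = w[k] / total_w
        for slot in slots:
            slot.prob = share / len(slots)
            out.append(slot)
    return out


def _clip(value: float, bounds_key: str) -> float:
    lo, hi = PARAM_BOUNDS[bounds_key]
    return min(max(value, lo), hi)


def _bounds_key(name: str) -> str:
    return name if name in PARAM_BOUNDS else "rho"


#: Log-range (relative to 1, the natural scale of the unit conventions)
#: from which parameters of newly added elements are drawn.  Freshly
#: duplicated or rewired genes start with kinetics of ordinary magnitude;
#: mutation then explores the full bounds multiplicatively.
ADDITION_SPREAD = math.log(20.0)


def _log_uniform(rng: np.random.Generator, bounds_key: str) -> float:
    lo, hi = PARAM_BOUNDS[bounds_key]
    lo = max(lo, math.exp(-ADDITION_SPREAD))
    hi = min(hi, math.exp(ADDITION_SPREAD))
    return math.exp(rng.uniform(math.log(lo), math.log(hi)))


def _random_interaction(network: NetworkSpec,
                        rng: np.random.Generator) -> InteractionSpec | None:
    """Draw a random permitted interaction, or None if saturated.

    The kind is drawn first (uniformly among kinds with at least one free
    slot), then the wiring uniformly within the kind — so protein-protein
    moves are as likely as transcriptional ones regardless of how many
    transcriptional wirings exist.
    """
    proteins = [s.id for s in network.species if s.role != ROLE_SWITCH]
    tf_pool = proteins + [network.switch.id]
    existing = {ix.key for ix in network.interactions}
    by_kind: dict[str, list] = {KIND_ACTIVATION: [], KIND_REPRESSION: [],
                                KIND_COMPLEX: []}
    for src in tf_pool:
        for tgt in proteins:
            for kind in (KIND_ACTIVATION, KIND_REPRESSION):
                if (kind, (src,), tgt) not in existing:
                    by_kind[kind].append((kind, (src,), tgt))
    for i, a in enumerate(proteins):
        for b in proteins[i + 1:]:
            if (KIND_COMPLEX, tuple(sorted((a, b)))) not in existing:
                by_kind[KIND_COMPLEX].append((KIND_COMPLEX, (a, b), b))
    kinds = [k for k, c in by_kind.items() if c]
    if not kinds:
        return None
    pool = by_kind[kinds[rng.integers(len(kinds))]]
    kind, sources, target = pool[rng.integers(len(pool))]
    if kind == KIND_ACTIVATION:
        return InteractionSpec(kind, sources, target,
                               rho=_log_uniform(rng, "rho"),
                               K=_log_uniform(rng, "K"),
                               hill_n=float(rng.integers(1, 5)))
    if kind == KIND_REPRESSION:
        return InteractionSpec(kind, sources, target,
                               K=_log_uniform(rng, "K"),
                               hill_n=float(rng.integers(1, 5)))
    return InteractionSpec(kind, sources, target,
                           k_on=_log_uniform(rng, "k_on"),
                           k_off=_log_uniform(rng, "k_off"),
                           delta_complex=_log_uniform(rng, "delta"))


def propose_mutation(network: NetworkSpec, schedule: list[MoveSlot],
                     rng: np.random.Generator
                     ) -> tuple[NetworkSpec, list[MutationMove]]:
    """Apply each scheduled move with its probability; return the mutant.

    Parameter changes are multiplicative log-normal steps clipped to the
    bounds; removals never touch immutable interactions (the gating of
    the G1/S transition by the inhibitor lives in the simulator and is
    not an interaction at all, so it can never be removed); additions
    draw a random permitted interaction or a new protein wired in by one.
    The result always passes validation.
    """
    net = network.copy()
    moves: list[MutationMove] = []
    removed: set[int] = set()
    for slot in schedule:
        if rng.random() >= slot.prob:
            continue
        if slot.kind == "parameter":
            if slot.index < 0:
                s = net.species[-1 - slot.index]
                old = getattr(s, slot.name)
                new = _clip(old * math.exp(LOGNORMAL_STEP_SIGMA *
                                           rng.standard_normal()),
                            _bounds_key(slot.name))
                setattr(s, slot.name, new)
                moves.append(MutationMove("parameter-change",
                                          f"{s.id}.{slot.name}",
                                          f"{old:.4g}->{new:.4g}"))
            else:
                if slot.index in removed:
                    continue
                ix = net.interactions[slot.index]
                old = getattr(ix, slot.name)
                key = "hill_n" if slot.name == "hill_n" else _bounds_key(
                    "delta" if slot.name == "delta_complex" else slot.name)
                new = _clip(old * math.exp(LOGNORMAL_STEP_SIGMA *
                                           rng.standard_normal()), key)
                if slot.name == "hill_n":
                    new = min(max(new, 1.0), PARAM_BOUNDS["hill_n"][1])
                setattr(ix, slot.name, new)
                moves.append(MutationMove("parameter-change",
                                          f"{ix.key}.{slot.name}",
                                          f"{old:.4g}->{new:.4g}"))
        elif slot.kind == "removal":
            if slot.index not in removed:
                removed.add(slot.index)
                moves.append(MutationMove("remove-interaction",
                                          str(net.interactions[slot.index].key)))
        elif slot.kind == "add-interaction":
            ix = _random_interaction(net, rng)
            if ix is not None:
                net.interactions.append(ix)
                moves.append(MutationMove("add-interaction", str(ix.key)))
        elif slot.kind == "add-species":
            existing = set(net.species_ids())
            k = 0
            while f"G{k}" in existing:
                k += 1
            sid = f"G{k}"
            net.species.append(SpeciesSpec(
                id=sid, role=ROLE_PROTEIN,
                delta=_log_uniform(rng, "delta"),
                rho0=_log_uniform(rng, "rho0"), init_conc=0.0))
            ix = _random_interaction(net, rng)
            # wire the newcomer in; resample until it touches the new gene
            for _ in range(50):
                if ix is not None and (sid in ix.sources or ix.target == sid):
                    break
                ix = _random_interaction(net, rng)
            if ix is not None:
                net.interactions.append(ix)
            moves.append(MutationMove("add-species", sid))
    if removed:
        net.interactions = [ix for i, ix in enumerate(net.interactions)
                            if i not in removed]
    net.validate()
    return net, moves


# ---------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------

def fitness_value(record: LineageRecord, objective: str,
                  V_target: float = 1.0) -> float:
    """Scalar fitness of a lineage record for one named objective."""
    if objective == "ndiv":
        return float(record.n_divisions)
    cyc = record.steady_cycles()
    if len(cyc) < 2:
        raise AnalysisError("degenerate record: fewer than 2 usable cycles")
    if objective == "cv_birth":
        v = cyc["V_birth"].to_numpy()
        return float(np.std(v, ddof=1) / np.mean(v))
    if objective == "target_residual":
        v = cyc["V_birth"].to_numpy()
        return float(np.mean((v - V_target) ** 2))
    if objective == "dv_slope":
        return float(fit_phase_slopes(record, "cycle").slope)
    raise EvolutionError(f"unknown objective {objective!r}")


def _fast_fitness(network, config: CycleConfig, seed) -> FitnessVector | None:
    """Kernel-only evaluation of (ndiv, cv_birth) without record frames.

    Identical to evaluating through :func:`simulate_lineage` (same kernel,
    same seed derivation) but skips the cycle-table construction, which
    dominates the cost of an evolutionary epoch.  Returns None on
    non-finite dynamics (caller decides whether to raise or penalize).
    """
    from . import _kernel
    from .simulator import _kernel_seed, compile_network

    compiled = compile_network(network)
    shortest = config.timer_fraction * config.tau * (1 - config.timer_noise_width)
    max_cycles = int(config.T_total / max(shortest, 10 * config.dt)) + 8
    out = _kernel.run_lineage_kernel(
        _kernel_seed(seed),
        compiled.x0, compiled.delta, compiled.rho0,
        compiled.asrc, compiled.atgt, compiled.arho, compiled.aK, compiled.an,
        compiled.rsrc, compiled.rtgt, compiled.rK, compiled.rn,
        compiled.cA, compiled.cB, compiled.cC, compiled.ckon, compiled.ckoff,
        compiled.idx_I,
        config.growth_rate, config.dt, config.T_total, config.V_init,
        0 if config.structure == "control" else 1,
        0 if config.sensing == "quantity" else 1,
        config.timer_fraction, config.timer_noise_width,
        config.growth_cv, config.partition_cv,
        1 if config.molecular_noise else 0, config.omega0,
        config.hazard.h_max, config.hazard.K_h, config.hazard.n_h,
        config.V_min, config.V_max, 0, 0.0, -1, -1.0, max_cycles, 0)
    status, capped, n_cyc = out[0], out[1], out[2]
    if status == _kernel.STATUS_NONFINITE:
        return None
    died = status == _kernel.STATUS_DIED
    fv = FitnessVector(ndiv=int(n_cyc), died=died, capped=bool(capped))
    v = out[5][config.warmup_cycles:n_cyc]          # post-warm-up V_birth
    if not died and len(v) >= 10:
        fv.cv_birth = float(np.std(v, ddof=1) / np.mean(v))
        if capped:
            frac = float(np.mean(out[12][:n_cyc]))
            fv.cv_birth += PENALTY_CV * frac
    return fv


def evaluate_individual(individual: Individual, config: CycleConfig,
                        objectives: tuple[str, ...] = ("ndiv", "cv_birth"),
                        seed: int | np.random.Generator = 0,
                        strict: bool = True) -> FitnessVector:
    """Simulate one lineage and fill the fitness vector with penalties.

    A lineage that dies keeps its (low) achieved NDiv and takes the
    penalty ceiling on CVBirth; a volume-capped lineage likewise takes
    the ceiling — cells pinned at the cut-off have no meaningful size
    distribution.  With ``strict`` false an integration failure (a mutant
    whose kinetics diverge) is treated as a nonviable network and
    penalized instead of raised, which is what the evolutionary loop
    wants.
    """
    try:
        rec = simulate_lineage(individual.network, config, seed=seed)
    except SimulationError as exc:
        if strict:
            raise SimulationError(
                f"individual {individual.uid}: {exc}") from exc
        fv = FitnessVector(ndiv=0, cv_birth=PENALTY_CV, died=True)
        for obj in objectives:
            if obj not in ("ndiv", "cv_birth"):
                fv.extras[obj] = PENALTY_CV
        individual.fitness = fv
        return fv
    fv = FitnessVector(ndiv=rec.n_divisions, died=rec.died, capped=rec.capped)
    penalized = rec.died
    if not penalized:
        try:
            fv.cv_birth = birth_cv(rec)
        except AnalysisError:
            penalized = True
    if penalized:
        fv.cv_birth = PENALTY_CV
    elif rec.capped:
        # graded penalty: brushing the volume cap once is a mild defect,
        # being pinned at the cap is as bad as dying
        frac = float(rec.cycles["capped"].mean())
        fv.cv_birth += PENALTY_CV * frac
    for obj in objectives:
        if obj in ("ndiv", "cv_birth"):
            continue
        try:
            fv.extras[obj] = PENALTY_CV if penalized else \
                fitness_value(rec, obj)
        except AnalysisError:
            fv.extras[obj] = PENALTY_CV
    individual.fitness = fv
    return fv


# ---------------------------------------------------------------------
# Pareto ranking and selection
# ---------------------------------------------------------------------

def _objective_matrix(population: list[Individual],
                      objectives: tuple[str, ...]) -> np.ndarray:
    for ind in population:
        if ind.fitness is None:
            raise EvolutionError("population contains unevaluated individuals")
    return np.array([[ind.fitness.objective(o) for o in objectives]
                     for ind in population])


def _dominates(a: np.ndarray, b: np.ndarray) -> bool:
    return bool(np.all(a >= b) and np.any(a > b))


def pareto_rank(population: list[Individual],
                objectives: tuple[str, ...] = ("ndiv", "cv_birth")
                ) -> np.ndarray:
    """Peeling-order Pareto ranks (rank 1 = non-dominated), all objectives
    oriented to maximize; a strictly better value in one objective with no
    worsening in any other constitutes dominance."""
    F = _objective_matrix(population, objectives)
    n = len(F)
    ranks = np.zeros(n, dtype=int)
    remaining = list(range(n))
    r = 0
    while remaining:
        r += 1
        front = [i for i in remaining
                 if not any(_dominates(F[j], F[i]) for j in remaining if j != i)]
        if not front:   # identical rows dominate nobody; peel them together
            front = list(remaining)
        for i in front:
            ranks[i] = r
        remaining = [i for i in remaining if i not in front]
    return ranks


def _niche_counts(F: np.ndarray, radius: float = SHARE_RADIUS) -> np.ndarray:
    """Fitness-sharing niche counts in normalized objective space."""
    span = np.ptp(F, axis=0)
    span[span == 0] = 1.0
    Z = F / span
    d = np.sqrt(((Z[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2))
    sh = np.clip(1.0 - d / radius, 0.0, None)
    return sh.sum(axis=1)


def select_survivors(population: list[Individual],
                     n_survivors: int | None = None,
                     objectives: tuple[str, ...] = ("ndiv", "cv_birth"),
                     rng: np.random.Generator | None = None,
                     mode: str = "pareto") -> list[Individual]:
    """Keep the best half: whole Pareto fronts, then fitness sharing.

    Fronts are peeled in rank order; within the boundary rank the
    individuals with the lowest niche counts (most isolated in normalized
    objective space) are retained, ties broken by the seeded RNG.  In
    single-objective mode individuals are simply sorted on the first
    objective.
    """
    if len(population) < 2:
        raise EvolutionError("population must hold at least 2 individuals")
    if n_survivors is None:
        n_survivors = len(population) // 2
    rng = rng or np.random.default_rng()
    if mode == "single":
        F = _objective_matrix(population, objectives[:1])[:, 0]
        order = np.lexsort((rng.random(len(F)), -F))
        return [population[i] for i in order[:n_survivors]]
    ranks = pareto_rank(population, objectives)
    F = _objective_matrix(population, objectives)
    survivors: list[int] = []
    for r in range(1, ranks.max() + 1):
        front = np.flatnonzero(ranks == r)
        if len(survivors) + len(front) <= n_survivors:
            survivors.extend(front.tolist())
        else:
            need = n_survivors - len(survivors)
            counts = _niche_counts(F[front])
            order = np.lexsort((rng.random(len(front)), counts))
            survivors.extend(front[order[:need]].tolist())
        if len(survivors) >= n_survivors:
            break
    return [population[i] for i in survivors]


# ---------------------------------------------------------------------
# The evolutionary loop
# ---------------------------------------------------------------------

@dataclass
class EvolutionTrajectory:
    log: pd.DataFrame
    checkpoints: dict[int, str]        # epoch -> serialized best network
    final_population: list[Individual]

    @property
    def best(self) -> Individual:
        pop = self.final_population
        return min(pop, key=lambda i: (i.fitness.cv_birth, -i.fitness.ndiv))


def run_evolution(seed_network: NetworkSpec, config: CycleConfig,
                  epochs: int = 100, population_size: int = 50,
                  objectives: tuple[str, ...] = ("ndiv", "cv_birth"),
                  mode: str = "pareto", seed: int = 0,
                  checkpoint_every: int = 50,
                  move_weights: dict | None = None) -> EvolutionTrajectory:
    """Evolve a population from a seed network for a number of epochs.

    Every epoch each network is simulated with a fresh derived seed and
    its fitness vector computed; half the population survives (Pareto
    fitness sharing or single-objective ranking), is duplicated to
    restore the population size, and the duplicates are mutated under the
    Drake-normalized schedule.  Fully reproducible under ``seed``.
    """
    if population_size < 2 or population_size % 2:
        raise EvolutionError("population size must be even and >= 2")
    seed_network.validate()
    rng = np.random.default_rng(seed)
    population = [Individual(network=seed_network.copy(), uid=i)
                  for i in range(population_size)]
    next_uid = population_size
    rows = []
    checkpoints: dict[int, str] = {}
    fast = all(o in ("ndiv", "cv_birth") for o in objectives)
    for epoch in range(epochs):
        for ind in population:
            ev_seed = int(rng.integers(2 ** 31 - 1))
            if fast:
                fv = _fast_fitness(ind.network, config, ev_seed)
                ind.fitness = fv if fv is not None else \
                    FitnessVector(ndiv=0, cv_birth=PENALTY_CV, died=True)
            else:
                evaluate_individual(ind, config, objectives, seed=ev_seed,
                                    strict=False)
        ranks = pareto_rank(population, objectives) if mode == "pareto" \
            else np.ones(len(population), dtype=int)
        cvs = np.array([i.fitness.cv_birth for i in population])
        ndivs = np.array([i.fitness.ndiv for i in population])
        rows.append({
            "epoch": epoch,
            "best_ndiv": int(ndivs.max()),
            "median_ndiv": float(np.median(ndivs)),
            "best_cv_birth": float(cvs.min()),
            "median_cv_birth": float(np.median(cvs)),
            "n_rank1": int((ranks == 1).sum()),
            "n_penalized": int(sum(i.fitness.died or i.fitness.capped
                                   for i in population)),
            "mean_n_interactions": float(np.mean(
                [len(i.network.interactions) for i in population])),
            "mean_n_species": float(np.mean(
                [len(i.network.species) for i in population])),
        })
        best = min(population, key=lambda i: (i.fitness.cv_birth,
                                              -i.fitness.ndiv))
        if epoch % checkpoint_every == 0 or epoch == epochs - 1:
            checkpoints[epoch] = serialize_network(best.network)
        survivors = select_survivors(population, population_size // 2,
                                     objectives, rng, mode=mode)
        offspring = []
        for parent in survivors:
            child_net = parent.network.copy()
            schedule = drake_rate_schedule(child_net, move_weights)
            child_net, _ = propose_mutation(child_net, schedule, rng)
            offspring.append(Individual(network=child_net, uid=next_uid))
            next_uid += 1
        population = [Individual(network=s.network, fitness=s.fitness,
                                 uid=s.uid) for s in survivors] + offspring
    # leave the last population evaluated
    for ind in population:
        if ind.fitness is None:
            evaluate_individual(ind, config, objectives,
                                seed=int(rng.integers(2 ** 31 - 1)),
                                strict=False)
    return EvolutionTrajectory(log=pd.DataFrame(rows),
                               checkpoints=checkpoints,
                               final_population=population)


def has_inhibitor_complex(network: NetworkSpec) -> bool:
    """True if any complex-formation interaction titrates the inhibitor
    (the signature of the mixed-feedback-loop size sensor)."""
    inh = network.inhibitor.id
    return any(ix.kind == KIND_COMPLEX and inh in ix.sources
               for ix in network.interactions)
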