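"""Mutation schedule, Pareto ranking, selection, and the evolution loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sizevolve as sv
from sizevolve.evolution import (DEFAULT_MOVE_WEIGHTS, EvolutionError,
                                 FitnessVector, Individual, PENALTY_CV,
                                 _niche_counts, evaluate_individual,
                                 fitness_value, has_inhibitor_complex,
                                 select_survivors)
from sizevolve.network import KIND_COMPLEX


class TestDrakeSchedule:
    def test_total_probability_is_one(self, seed_net, mfl_net):
        for net in (seed_net, mfl_net):
            sched = sv.drake_rate_schedule(net)
            assert sum(s.prob for s in sched) == pytest.approx(1.0)

    def test_parameter_only_weights_split_uniformly(self, mfl_net):
        sched = sv.drake_rate_schedule(
            mfl_net, {"parameter": 1.0, "removal": 0.0, "addition": 0.0})
        n = len(sched)
        assert all(s.kind == "parameter" for s in sched)
        assert all(s.prob == pytest.approx(1.0 / n) for s in sched)

    def test_mean_applied_moves_is_one(self, mfl_net, rng):
        """Drake normalization: one mutation per network per epoch."""
        sched = sv.drake_rate_schedule(mfl_net)
        probs = np.array([s.prob for s in sched])
        counts = (rng.random((10_000, len(probs))) < probs).sum(axis=1)
        assert counts.mean() == pytest.approx(1.0, abs=0.03)

    def test_growing_the_network_halves_per_element_rates(self, seed_net):
        sched1 = sv.drake_rate_schedule(
            seed_net, {"parameter": 1.0, "removal": 0.0, "addition": 0.0})
        double = seed_net.copy()
        double.interactions[0].mutable = True
        from sizevolve.network import InteractionSpec, KIND_ACTIVATION, SpeciesSpec
        double.species.append(SpeciesSpec("X", "protein", delta=1.0, rho0=1.0))
        sched2 = sv.drake_rate_schedule(
            double, {"parameter": 1.0, "removal": 0.0, "addition": 0.0})
        assert len(sched2) == len(sched1) + 2      # delta and rho0 of X
        assert sched2[0].prob == pytest.approx(
            sched1[0].prob * len(sched1) / len(sched2))


class TestMutation:
    def test_parameter_only_schedule_preserves_topology(self, mfl_net, rng):
        sched = sv.drake_rate_schedule(
            mfl_net, {"parameter": 1.0, "removal": 0.0, "addition": 0.0})
        mut, moves = sv.propose_mutation(mfl_net, sched, rng)
        assert len(mut.interactions) == len(mfl_net.interactions)
        assert [ix.key for ix in mut.interactions] == \
            [ix.key for ix in mfl_net.interactions]
        assert all(m.kind == "parameter-change" for m in moves)

    def test_immutable_interaction_never_removed(self, rng):
        net = sv.seed_network()
        net.interactions[0].mutable = False
        for _ in range(300):
            sched = sv.drake_rate_schedule(net)
            mut, _ = sv.propose_mutation(net, sched, rng)
            keys = [ix.key for ix in mut.interactions]
            assert net.interactions[0].key in keys

    def test_mutants_always_validate(self, seed_net):
        """10^4 successive random moves never orphan species or break
        invariants (validation-preservation)."""
        rng = np.random.default_rng(123)
        net = seed_net.copy()
        applied = 0
        while applied < 10_000:
            sched = sv.drake_rate_schedule(net)
            net, moves = sv.propose_mutation(net, sched, rng)
            applied += max(len(moves), 1)
            net.validate()       # raises on any broken invariant
        assert len(net.species) >= 2

    def test_original_network_untouched(self, mfl_net, rng):
        doc = sv.serialize_network(mfl_net)
        for _ in range(50):
            sched = sv.drake_rate_schedule(mfl_net)
            sv.propose_mutation(mfl_net, sched, rng)
        assert sv.serialize_network(mfl_net) == doc


class TestFitness:
    def test_cv_birth_zero_for_constant_births(self):
        rec = sv.ideal_rule_lineage("timer", 30, noise=0.0, seed=0)
        assert fitness_value(rec, "cv_birth") == 0.0

    def test_sizer_oracle_slope_objective(self):
        rec = sv.ideal_rule_lineage("sizer", 500, noise=0.05, seed=1)
        assert fitness_value(rec, "dv_slope") == pytest.approx(-1.0, abs=0.05)

    def test_target_residual_zero_at_target(self):
        rec = sv.ideal_rule_lineage("timer", 30, noise=0.0, seed=0)
        v0 = rec.cycles["V_birth"].iloc[0]
        assert fitness_value(rec, "target_residual", V_target=v0) == \
            pytest.approx(0.0, abs=1e-12)

    def test_ndiv_counts_divisions(self):
        rec = sv.ideal_rule_lineage("adder", 25, noise=0.05, seed=0)
        assert fitness_value(rec, "ndiv") == 25

    def test_seed_network_capped_variant_penalized(self):
        net = sv.seed_network()
        net.interactions[0].rho = 500.0
        net.get_species("I").delta = 0.05
        ind = Individual(network=net)
        fv = evaluate_individual(ind, sv.CycleConfig(), seed=0)
        # pinned at the volume cap: graded penalty near the ceiling
        assert fv.capped and fv.cv_birth > 0.5 * PENALTY_CV

    def test_cap_penalty_graded_by_capped_fraction(self, mfl_net):
        """A lineage that only brushes the cap occasionally is penalized
        far less than one pinned at the cap."""
        brushing = evaluate_individual(
            Individual(network=mfl_net),
            sv.CycleConfig(V_max=2.2), seed=3)
        pinned = evaluate_individual(
            Individual(network=mfl_net),
            sv.CycleConfig(V_max=1.3), seed=3)
        assert brushing.capped
        assert brushing.cv_birth < 2.0
        assert pinned.cv_birth > brushing.cv_birth

    def test_shrinking_lineage_dies_with_few_divisions(self):
        net = sv.seed_network()
        net.interactions[0].rho = 1e-3
        fv = evaluate_individual(Individual(network=net), sv.CycleConfig(),
                                 seed=0)
        assert fv.died and fv.ndiv < 20 and fv.cv_birth == PENALTY_CV

    def test_homeostatic_network_unpenalized(self, mfl_net):
        fv = evaluate_individual(Individual(network=mfl_net),
                                 sv.CycleConfig(), seed=0)
        assert not fv.died and not fv.capped
        assert 0 < fv.cv_birth < 1
        assert fv.ndiv > 25


def _pop(fitnesses):
    return [Individual(network=None, fitness=FitnessVector(ndiv=n, cv_birth=c),
                       uid=i) for i, (n, c) in enumerate(fitnesses)]


def _brute_force_ranks(F):
    """O(n^2) dominance peeling oracle on a maximize-all matrix."""
    n = len(F)
    dominated_by = [
        {j for j in range(n) if j != i
         and all(F[j][k] >= F[i][k] for k in range(len(F[i])))
         and any(F[j][k] > F[i][k] for k in range(len(F[i])))}
        for i in range(n)]
    ranks = [0] * n
    assigned = set()
    r = 0
    while len(assigned) < n:
        r += 1
        front = [i for i in range(n) if i not in assigned
                 and dominated_by[i] <= assigned]
        for i in front:
            ranks[i] = r
        assigned |= set(front)
    return ranks


class TestPareto:
    def test_single_individual_rank_one(self):
        assert sv.pareto_rank(_pop([(3, 0.1)])).tolist() == [1]

    def test_dominance_example(self):
        ranks = sv.pareto_rank(_pop([(2, 0.1), (3, 0.05)]))
        assert ranks.tolist() == [2, 1]

    def test_mutually_nondominated_pair(self):
        ranks = sv.pareto_rank(_pop([(2, 0.05), (3, 0.1)]))
        assert ranks.tolist() == [1, 1]

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 64))
        ndiv = rng.integers(0, 6, n)
        cv = rng.choice([0.05, 0.1, 0.3, 10.0], n)
        pop = _pop(list(zip(ndiv, cv)))
        ours = sv.pareto_rank(pop).tolist()
        F = [[float(n_), -float(c_)] for n_, c_ in zip(ndiv, cv)]
        assert ours == _brute_force_ranks(F)


class TestSelection:
    def test_dominator_survives(self, rng):
        pop = _pop([(2, 0.1), (3, 0.05)])
        surv = select_survivors(pop, 1, rng=rng)
        assert [s.uid for s in surv] == [1]

    def test_count_contract_with_identical_fitness(self, rng):
        pop = _pop([(3, 0.1)] * 8)
        surv = select_survivors(pop, rng=rng)
        assert len(surv) == 4

    def test_never_prefers_dominated_over_dominator(self, rng):
        pop = _pop([(5, 0.05), (1, 0.5), (1, 0.5), (1, 0.5)])
        for _ in range(20):
            surv = select_survivors(pop, 2, rng=rng)
            assert 0 in {s.uid for s in surv}

    def test_isolated_point_preferred_over_crowded_cluster(self, rng):
        # three mutually nondominated points; two nearly identical
        pop = _pop([(10, 0.50), (9.9, 0.499), (1, 0.05)])
        kept = [frozenset(s.uid for s in select_survivors(pop, 2, rng=rng))
                for _ in range(10)]
        assert all(2 in k for k in kept)

    def test_sharing_kernel_counts(self):
        F = np.array([[10.0, -0.50], [9.9, -0.499], [1.0, -0.05]])
        counts = _niche_counts(F)
        assert counts[2] < counts[0] and counts[2] < counts[1]

    def test_tiny_population_rejected(self, rng):
        with pytest.raises(EvolutionError):
            select_survivors(_pop([(1, 0.1)]), rng=rng)


class TestRunEvolution:
    def test_fixed_seed_reproducible(self, seed_net):
        cfg = sv.CycleConfig(T_total=20.0)
        a = sv.run_evolution(seed_net, cfg, epochs=5, population_size=10,
                             seed=3)
        b = sv.run_evolution(seed_net, cfg, epochs=5, population_size=10,
                             seed=3)
        assert a.log.equals(b.log)
        assert a.checkpoints == b.checkpoints

    def test_population_size_constant_and_log_complete(self, seed_net):
        cfg = sv.CycleConfig(T_total=20.0)
        traj = sv.run_evolution(seed_net, cfg, epochs=6, population_size=8,
                                seed=0)
        assert len(traj.final_population) == 8
        assert traj.log["epoch"].tolist() == list(range(6))

    def test_single_objective_mode_runs(self, seed_net):
        cfg = sv.CycleConfig(T_total=20.0)
        traj = sv.run_evolution(seed_net, cfg, epochs=4, population_size=8,
                                objectives=("ndiv",), mode="single", seed=1)
        assert traj.log["best_ndiv"].iloc[-1] >= traj.log["best_ndiv"].iloc[0] - 2


def test_has_inhibitor_complex(mfl_net, seed_net):
    assert has_inhibitor_complex(mfl_net)
    assert not has_inhibitor_complex(seed_net)
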