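import random

import pytest

from elucid.chem_graph import from_smiles, parse_formula
from elucid.ea_engine import (
    EAConfig,
    Evaluator,
    Individual,
    Problem,
    aggregate_runs,
    check_termination,
    initialize,
    run,
    step,
    tournament_select,
)
from elucid.fixtures import make_closed_loop_problem
from elucid.hose_index import build_index
from elucid.judges import FitnessRecord, JudgeConfig, Peak, Spectrum

from _brute import enumerate_constitutions


def _record(total):
    return FitnessRecord(0.0, total, None, None, False, total)


def _individual(total, key):
    return Individual(from_smiles("C"), _record(total), key)


class TestEAConfig:
    def test_niche_size_must_exceed_base(self):
        with pytest.raises(ValueError):
            EAConfig(population_size=16, niche_size=16)

    def test_some_termination_criterion_required(self):
        with pytest.raises(ValueError):
            EAConfig(max_generations=None)


class TestTournamentSelect:
    def test_strictly_ordered_costs_keep_top(self):
        pop = [_individual(t, f"k{t}") for t in range(10)]
        survivors = tournament_select(pop, 4, random.Random(0))
        assert sorted(ind.record.total for ind in survivors) == [6, 7, 8, 9]

    def test_all_equal_costs_tie_break_by_key(self):
        pop = [_individual(1.0, key) for key in "fedcba"]
        survivors = tournament_select(pop, 3, random.Random(0))
        assert [ind.key for ind in survivors] == ["a", "b", "c"]

    def test_target_equals_population_is_identity(self):
        pop = [_individual(t, f"k{t}") for t in range(5)]
        assert tournament_select(pop, 5, random.Random(0)) == sorted(
            pop, key=lambda i: -i.record.total
        )


class TestInitialize:
    def _problem_and_evaluator(self, shift_index):
        ethanol = from_smiles("CCO")
        formula, spectrum, answer = make_closed_loop_problem(ethanol, shift_index)
        evaluator = Evaluator(spectrum, shift_index, None,
                              JudgeConfig(mode="nmr_only"))
        return Problem(formula, spectrum, answer), evaluator

    def test_population_size_and_validity(self, shift_index):
        problem, evaluator = self._problem_and_evaluator(shift_index)
        config = EAConfig(max_generations=10, seed=4)
        state = initialize(problem, config, evaluator, random.Random(4))
        assert len(state.population) == config.population_size
        keys = set()
        for ind in state.population:
            ind.graph.validate(problem.formula)
            keys.add(ind.key)
        assert len(keys) <= 2  # C2H6O has exactly two constitutions

    def test_seeded_determinism(self, shift_index):
        problem, _ = self._problem_and_evaluator(shift_index)
        config = EAConfig(max_generations=10, seed=9)
        pops = []
        for _ in range(2):
            evaluator = Evaluator(problem.spectrum, shift_index, None,
                                  JudgeConfig(mode="nmr_only"))
            state = initialize(problem, config, evaluator, random.Random(9))
            pops.append([ind.key for ind in state.population])
        assert pops[0] == pops[1]

    def test_single_individual_run_terminates(self, shift_index):
        problem, _ = self._problem_and_evaluator(shift_index)
        config = EAConfig(population_size=1, niche_size=2, max_generations=5, seed=0)
        sol = run(problem, shift_index, None, JudgeConfig(mode="nmr_only"), config)
        assert len(sol) >= 1


class TestStepAndNiche:
    class ScriptedEvaluator:
        """Returns totals from a fixed schedule; lets tests script stagnation."""

        def __init__(self, schedule):
            self.schedule = list(schedule)
            self.calls = 0
            self.archive = {}

        def __call__(self, g):
            total = self.schedule[min(self.calls, len(self.schedule) - 1)]
            self.calls += 1
            return Individual(g, _record(total), f"s{self.calls}")

    def _stagnant_state(self, config):
        evaluator = self.ScriptedEvaluator([0.5])
        population = [_individual(0.5, f"k{i}") for i in range(config.population_size)]
        from elucid.ea_engine import EvolutionState

        return (
            EvolutionState(
                generation=0,
                population=population,
                best_history=[0.5],
                target_size=config.population_size,
            ),
            evaluator,
        )

    def test_population_doubles_then_contracts(self, shift_index):
        ethanol = from_smiles("CCO")
        formula, spectrum, _ = make_closed_loop_problem(ethanol, shift_index)
        evaluator = Evaluator(spectrum, shift_index, None, JudgeConfig(mode="nmr_only"))
        problem = Problem(formula, spectrum)
        config = EAConfig(max_generations=100, seed=2)
        rng = random.Random(2)
        state = initialize(problem, config, evaluator, rng)
        n_before = len(state.population)
        step(state, config, evaluator, rng)
        assert len(state.population) in (n_before, config.niche_size)
        assert state.generation == 1

    def test_stagnation_triggers_niche_expansion(self):
        config = EAConfig(max_generations=100, seed=0)
        state, evaluator = self._stagnant_state(config)
        rng = random.Random(0)
        for _ in range(config.stagnation_window):
            step(state, config, evaluator, rng)
        assert state.niche_active
        assert state.target_size == config.niche_size
        assert len(state.population) == config.niche_size

    def test_failed_niche_trial_contracts_to_base(self):
        config = EAConfig(max_generations=100, seed=0)
        state, evaluator = self._stagnant_state(config)
        rng = random.Random(0)
        for _ in range(config.stagnation_window + config.niche_window):
            step(state, config, evaluator, rng)
        assert not state.niche_active
        assert state.target_size == config.population_size
        assert len(state.population) == config.population_size

    def test_improvement_during_niche_keeps_expansion(self):
        config = EAConfig(max_generations=100, seed=0)
        state, evaluator = self._stagnant_state(config)
        rng = random.Random(0)
        for _ in range(config.stagnation_window):
            step(state, config, evaluator, rng)
        assert state.niche_active
        # next offspring batch contains an improvement
        evaluator.schedule = [0.9]
        step(state, config, evaluator, rng)
        assert not state.niche_active
        assert state.target_size == config.niche_size
        assert state.best_history[-1] == 0.9

    def test_best_history_never_decreases(self, shift_index, fragment_model,
                                          closed_loop):
        formula, spectrum, answer = closed_loop
        problem = Problem(formula, spectrum, answer)
        sol = run(problem, shift_index, fragment_model, JudgeConfig(),
                  EAConfig(max_generations=150, seed=5))
        history = sol.meta["best_history"]
        assert all(b >= a for a, b in zip(history, history[1:]))


class TestTermination:
    def test_max_generations(self):
        from elucid.ea_engine import EvolutionState

        config = EAConfig(max_generations=3000)
        state = EvolutionState(3000, [], [1.0])
        assert check_termination(state, config) == "max_generations"

    def test_max_fitness(self):
        from elucid.ea_engine import EvolutionState

        config = EAConfig(max_generations=10**6, max_fitness=1.0)
        state = EvolutionState(5, [], [1.0])
        assert check_termination(state, config) == "max_fitness"

    def test_no_criterion_met(self):
        from elucid.ea_engine import EvolutionState

        config = EAConfig(max_generations=3000)
        state = EvolutionState(10, [], [0.2])
        assert check_termination(state, config) is None


class TestRun:
    def test_zero_generations_reports_initial_population(self, shift_index):
        ethanol = from_smiles("CCO")
        formula, spectrum, answer = make_closed_loop_problem(ethanol, shift_index)
        sol = run(Problem(formula, spectrum, answer), shift_index, None,
                  JudgeConfig(mode="nmr_only"), EAConfig(max_generations=0, seed=1))
        assert sol.meta["generations"] == 0
        assert 1 <= len(sol) <= 2

    def test_small_space_fully_traversed(self, shift_index):
        """C2H6O: both constitutions appear in the archive of a short run."""
        ethanol = from_smiles("CCO")
        formula, spectrum, answer = make_closed_loop_problem(ethanol, shift_index)
        sol = run(Problem(formula, spectrum, answer), shift_index, None,
                  JudgeConfig(mode="nmr_only"), EAConfig(max_generations=50, seed=1))
        expected = {g.key for g in enumerate_constitutions(parse_formula("C2H6O"))}
        assert {s.key for s in sol.solutions} == expected
        assert sol.answer_rank == 1

    def test_identical_seed_identical_solution_set(self, shift_index, fragment_model,
                                                   closed_loop):
        formula, spectrum, answer = closed_loop
        problem = Problem(formula, spectrum, answer)
        sols = [
            run(problem, shift_index, fragment_model, JudgeConfig(),
                EAConfig(max_generations=60, seed=12))
            for _ in range(2)
        ]
        assert [(s.rank, s.key, s.record) for s in sols[0].solutions] == [
            (s.rank, s.key, s.record) for s in sols[1].solutions
        ]


class TestAggregate:
    def test_duplicate_runs_idempotent(self, shift_index, closed_loop):
        formula, spectrum, answer = closed_loop
        problem = Problem(formula, spectrum, answer)
        sol = run(problem, shift_index, None, JudgeConfig(mode="nmr_only"),
                  EAConfig(max_generations=40, seed=3))
        merged = aggregate_runs([sol, sol])
        assert [(s.rank, s.key) for s in merged.solutions] == [
            (s.rank, s.key) for s in sol.solutions
        ]

    def test_union_of_two_runs(self, shift_index, closed_loop):
        formula, spectrum, answer = closed_loop
        problem = Problem(formula, spectrum, answer)
        sols = [
            run(problem, shift_index, None, JudgeConfig(mode="nmr_only"),
                EAConfig(max_generations=40, seed=s))
            for s in (3, 4)
        ]
        merged = aggregate_runs(sols)
        assert {s.key for s in merged.solutions} == (
            {s.key for s in sols[0].solutions} | {s.key for s in sols[1].solutions}
        )

    def test_mismatched_problems_rejected(self, shift_index):
        ethanol = from_smiles("CCO")
        f1, s1, a1 = make_closed_loop_problem(ethanol, shift_index)
        sol1 = run(Problem(f1, s1, a1), shift_index, None,
                   JudgeConfig(mode="nmr_only"), EAConfig(max_generations=5, seed=0))
        propanol = from_smiles("CCCO")
        f2, s2, a2 = make_closed_loop_problem(propanol, shift_index)
        sol2 = run(Problem(f2, s2, a2), shift_index, None,
                   JudgeConfig(mode="nmr_only"), EAConfig(max_generations=5, seed=0))
        with pytest.raises(ValueError):
            aggregate_runs([sol1, sol2])


class TestNpRankingImprovement:
    """The ranking mechanism: NMR-tied candidates reordered by NP-likeness."""

    def _tied_pair_setup(self):
        from elucid.hose_index import ShiftIndex, ShiftIndexEntry, hose_code

        dee = from_smiles("CCOCC")     # diethyl ether
        mpe = from_smiles("CCCOC")     # methyl propyl ether
        # same attached-H classes (2x CH3, 2x CH2); index every 1-sphere
        # environment of both isomers at the same mean per class
        codes = {}
        for g in (dee, mpe):
            for i in g.carbons():
                mean = 20.0 if g.hydrogens[i] == 3 else 60.0
                codes[hose_code(g, i, 1)] = ShiftIndexEntry(2, mean, 0.0, 5.0)
        index = ShiftIndex({1: codes})
        spectrum = Spectrum([Peak(20.0, 3, 2), Peak(60.0, 2, 2)])
        spectrum.validate(dee.element_counts())
        return dee, mpe, index, spectrum

    def test_nmr_tied_pair_strictly_reordered_in_nmr_np_mode(self, np_corpora):
        from elucid.ea_engine import _rank_archive
        from elucid.judges import evaluate, np_judge
        from elucid.np_model import train_fragment_model

        dee, mpe, index, spectrum = self._tied_pair_setup()
        # train with the ether pair included so the two isomers' fragment
        # profiles are guaranteed to be represented (and to differ)
        np_set, syn_set = np_corpora
        fragment_model = train_fragment_model(np_set + [dee], syn_set + [mpe])
        np_norms = {
            g.key: np_judge(g, fragment_model, JudgeConfig())[1] for g in (dee, mpe)
        }
        assert np_norms[dee.key] != np_norms[mpe.key]
        higher = dee if np_norms[dee.key] > np_norms[mpe.key] else mpe

        for mode in ("nmr_only", "nmr_np"):
            config = JudgeConfig(mode=mode)
            model = fragment_model if mode == "nmr_np" else None
            archive = {
                g.key: (g, evaluate(g, spectrum, index, model, config))
                for g in (dee, mpe)
            }
            assert all(rec.nmr_norm == 1.0 for _, rec in archive.values())
            ranked = _rank_archive(archive, None)
            if mode == "nmr_only":
                assert [s.rank for s in ranked] == [1, 1]  # tie shares rank 1
            else:
                assert [s.rank for s in ranked] == [1, 2]
                assert ranked[0].key == higher.key
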