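"""Evolutionary search over constitutional isomer space.

One generation: every individual is mutated once, doubling the
population; all offspring are evaluated; round-robin tournament
selection (all-pairs win counting) keeps the fittest back down to the
target size.  After five generations without improvement of the best
fitness, a niche (vicinity) search injects four single-mutation
offspring of each of the two fittest individuals, expanding the
population from 16 to 24 for a five-generation trial; if the trial also
stalls, tournament selection contracts the population back to 16.
Every distinct constitution ever evaluated is archived with its cost,
and the archive -- not the final population -- is ranked into the
solution set, so the search reports all isomers traversed.
"""

from __future__ import annotations

import random
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .chem_graph import (
    MolecularGraph,
    format_formula,
    is_same_constitution,
    mutate,
    random_structure,
)
from .hose_index import ShiftIndex
from .judges import FitnessRecord, JudgeConfig, Spectrum, evaluate
from .np_model import FragmentModel

__all__ = [
    "EAConfig",
    "Problem",
    "Individual",
    "EvolutionState",
    "RankedSolution",
    "SolutionSet",
    "Evaluator",
    "initialize",
    "step",
    "tournament_select",
    "niche_inject",
    "check_termination",
    "run",
    "aggregate_runs",
]


@dataclass
class EAConfig:
    """Search hyperparameters (defaults follow the published scheme)."""

    population_size: int = 16
    niche_size: int = 24
    stagnation_window: int = 5
    niche_window: int = 5
    max_generations: int = 3000
    max_runtime: Optional[float] = None  # seconds
    max_fitness: Optional[float] = None
    max_stagnant: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.niche_size <= self.population_size:
            raise ValueError("niche-expanded size must exceed the base size")
        if self.population_size < 1 or self.stagnation_window < 1:
            raise ValueError("population size and windows must be positive")
        if (
            self.max_generations is None
            and self.max_runtime is None
            and self.max_fitness is None
            and self.max_stagnant is None
        ):
            raise ValueError("at least one termination criterion must be enabled")


@dataclass
class Problem:
    """An elucidation problem: formula + spectrum (+ optional known answer)."""

    formula: Dict[str, int]
    spectrum: Spectrum
    answer: Optional[MolecularGraph] = None

    def validate(self) -> None:
        self.spectrum.validate(self.formula)
        if self.answer is not None:
            self.answer.validate(self.formula)

    def signature(self) -> str:
        """Identity used to check that runs being merged share a problem."""
        peaks = sorted(
            (p.shift, p.n_h, p.multiplicity) for p in self.spectrum.peaks
        )
        return f"{format_formula(self.formula)}|{peaks!r}"


@dataclass
class Individual:
    graph: MolecularGraph
    record: FitnessRecord
    key: str


class Evaluator:
    """Judge wrapper with a per-constitution cache.

    Re-evaluating the same constitution is deterministic, so fitness is
    cached by canonical key; the cache doubles as the archive of all
    constitutions traversed.
    """

    def __init__(
        self,
        spectrum: Spectrum,
        index: ShiftIndex,
        model: Optional[FragmentModel],
        config: JudgeConfig,
    ) -> None:
        self.spectrum = spectrum
        self.index = index
        self.model = model
        self.config = config
        self.archive: Dict[str, Tuple[MolecularGraph, FitnessRecord]] = {}

    def __call__(self, g: MolecularGraph) -> Individual:
        key = g.key
        cached = self.archive.get(key)
        if cached is None:
            record = evaluate(g, self.spectrum, self.index, self.model, self.config)
            self.archive[key] = (g, record)
        else:
            record = cached[1]
        return Individual(g, record, key)


@dataclass
class EvolutionState:
    generation: int
    population: List[Individual]
    best_history: List[float]
    stagnation: int = 0
    niche_active: bool = False
    niche_generations: int = 0
    target_size: int = 16
    termination_reason: Optional[str] = None

    @property
    def best(self) -> Individual:
        return max(self.population, key=lambda ind: (ind.record.total, ind.key))


@dataclass(frozen=True)
class RankedSolution:
    rank: int
    key: str
    graph: MolecularGraph
    record: FitnessRecord
    is_answer: bool = False


@dataclass
class SolutionSet:
    """Deduplicated candidates ranked by total cost, best first.

    Ties share the better (competition) rank; within a tie, entries are
    ordered by canonical key for determinism.
    """

    solutions: List[RankedSolution]
    problem_signature: str
    answer_rank: Optional[int] = None
    meta: Dict[str, object] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.solutions)

    @property
    def top(self) -> RankedSolution:
        return self.solutions[0]


# ---------------------------------------------------------------------------
# Core loop operations
# ---------------------------------------------------------------------------


def initialize(
    problem: Problem,
    config: EAConfig,
    evaluator: Evaluator,
    rng: random.Random,
) -> EvolutionState:
    """Seed the population by mutating one random structure of the formula."""
    problem.validate()
    seed_graph = random_structure(problem.formula, rng)
    population = [
        evaluator(mutate(seed_graph, rng)) for _ in range(config.population_size)
    ]
    state = EvolutionState(
        generation=0,
        population=population,
        best_history=[],
        target_size=config.population_size,
    )
    state.best_history.append(state.best.record.total)
    return state


def tournament_select(
    population: Sequence[Individual],
    target: int,
    rng: random.Random,
) -> List[Individual]:
    """Round-robin (all-pairs) tournament: most pairwise wins survive.

    A strictly higher total cost wins each pairing.  Survivors are the
    top ``target`` by win count, ties broken by (total cost, canonical
    key) so selection is deterministic; ``rng`` is accepted for
    interface symmetry but the all-pairs bracket needs no draws.
    """
    if target > len(population):
        raise ValueError("target size exceeds population size")
    totals = [ind.record.total for ind in population]
    wins = [0] * len(population)
    for i in range(len(population)):
        for j in range(i + 1, len(population)):
            if totals[i] > totals[j]:
                wins[i] += 1
            elif totals[j] > totals[i]:
                wins[j] += 1
    order = sorted(
        range(len(population)),
        key=lambda k: (-wins[k], -totals[k], population[k].key),
    )
    return [population[k] for k in order[:target]]


def step(
    state: EvolutionState,
    config: EAConfig,
    evaluator: Evaluator,
    rng: random.Random,
) -> EvolutionState:
    """One generation: mutate every individual, evaluate, select back down."""
    offspring = [evaluator(mutate(ind.graph, rng)) for ind in state.population]
    doubled = list(state.population) + offspring
    state.population = tournament_select(doubled, state.target_size, rng)
    state.generation += 1

    best = state.best.record.total
    prev_best = state.best_history[-1] if state.best_history else float("-inf")
    state.best_history.append(max(best, prev_best))
    improved = best > prev_best
    if improved:
        state.stagnation = 0
        if state.niche_active:
            # improvement during the niche trial: keep the expanded
            # population, leave niche mode
            state.niche_active = False
            state.niche_generations = 0
    else:
        state.stagnation += 1

    if state.niche_active:
        state.niche_generations += 1
        if state.niche_generations >= config.niche_window:
            # trial failed: contract back to the base size
            state.population = tournament_select(
                state.population, config.population_size, rng
            )
            state.target_size = config.population_size
            state.niche_active = False
            state.niche_generations = 0
            state.stagnation = 0
    elif state.stagnation >= config.stagnation_window:
        niche_inject(state, config, evaluator, rng)
    return state


def niche_inject(
    state: EvolutionState,
    config: EAConfig,
    evaluator: Evaluator,
    rng: random.Random,
) -> None:
    """Vicinity search: add mutants of the two fittest individuals.

    Injects ``niche_size - population_size`` fresh individuals (split
    evenly over the top two, i.e. 4 + 4 for the default 16 -> 24) and
    starts the niche trial window.  If the population is already
    expanded, it is first contracted to the base size.
    """
    if state.target_size > config.population_size:
        state.population = tournament_select(
            state.population, config.population_size, rng
        )
        state.target_size = config.population_size
    elites = sorted(
        state.population,
        key=lambda ind: (-ind.record.total, ind.key),
    )[:2]
    n_fresh = config.niche_size - config.population_size
    fresh: List[Individual] = []
    for k in range(n_fresh):
        parent = elites[k % len(elites)]
        fresh.append(evaluator(mutate(parent.graph, rng)))
    state.population = list(state.population) + fresh
    state.target_size = config.niche_size
    state.niche_active = True
    state.niche_generations = 0
    state.stagnation = 0


def check_termination(
    state: EvolutionState,
    config: EAConfig,
    started_at: Optional[float] = None,
) -> Optional[str]:
    """Return the name of the first met termination criterion, else None."""
    if config.max_generations is not None and state.generation >= config.max_generations:
        return "max_generations"
    if config.max_fitness is not None and state.best_history:
        if state.best_history[-1] >= config.max_fitness:
            return "max_fitness"
    if config.max_runtime is not None and started_at is not None:
        if time.monotonic() - started_at >= config.max_runtime:
            return "max_runtime"
    if config.max_stagnant is not None and state.stagnation >= config.max_stagnant:
        return "max_stagnant"
    return None


# ---------------------------------------------------------------------------
# Full runs and run aggregation
# ---------------------------------------------------------------------------


def run(
    problem: Problem,
    index: ShiftIndex,
    model: Optional[FragmentModel],
    judge_config: JudgeConfig,
    ea_config: EAConfig,
) -> SolutionSet:
    """One full evolution; returns the ranked archive of all constitutions."""
    rng = random.Random(ea_config.seed)
    evaluator = Evaluator(problem.spectrum, index, model, judge_config)
    started_at = time.monotonic()
    state = initialize(problem, ea_config, evaluator, rng)
    while True:
        reason = check_termination(state, ea_config, started_at)
        if reason is not None:
            state.termination_reason = reason
            break
        step(state, ea_config, evaluator, rng)
    solutions = _rank_archive(evaluator.archive, problem.answer)
    meta = {
        "seed": ea_config.seed,
        "generations": state.generation,
        "termination": state.termination_reason,
        "archive_size": len(evaluator.archive),
        "mode": judge_config.mode,
        "best_history": state.best_history,
    }
    answer_rank = next((s.rank for s in solutions if s.is_answer), None)
    return SolutionSet(solutions, problem.signature(), answer_rank, meta)


def _rank_archive(
    archive: Dict[str, Tuple[MolecularGraph, FitnessRecord]],
    answer: Optional[MolecularGraph],
) -> List[RankedSolution]:
    answer_key = answer.key if answer is not None else None
    items = sorted(
        archive.items(), key=lambda kv: (-kv[1][1].total, kv[0])
    )
    solutions: List[RankedSolution] = []
    rank = 0
    prev_total = None
    for pos, (key, (g, record)) in enumerate(items, start=1):
        if record.total != prev_total:
            rank = pos
            prev_total = record.total
        is_answer = answer_key is not None and key == answer_key
        if is_answer and answer is not None and not is_same_constitution(g, answer):
            # canonical key and VF2 isomorphism must agree; a mismatch
            # means a canonicalization bug, not an answer hit
            raise AssertionError("canonical key matched a non-isomorphic answer")
        solutions.append(RankedSolution(rank, key, g, record, is_answer))
    return solutions


def aggregate_runs(solution_sets: Sequence[SolutionSet]) -> SolutionSet:
    """Merge several runs of the same problem, keeping each constitution's best cost."""
    if not solution_sets:
        raise ValueError("need at least one run to aggregate")
    signature = solution_sets[0].problem_signature
    merged: Dict[str, Tuple[MolecularGraph, FitnessRecord]] = {}
    answer_key: Optional[str] = None
    for sol_set in solution_sets:
        if sol_set.problem_signature != signature:
            raise ValueError("cannot aggregate runs over different problems")
        for s in sol_set.solutions:
            if s.is_answer:
                answer_key = s.key
            best = merged.get(s.key)
            if best is None or s.record.total > best[1].total:
                merged[s.key] = (s.graph, s.record)
    items = sorted(merged.items(), key=lambda kv: (-kv[1][1].total, kv[0]))
    solutions: List[RankedSolution] = []
    rank = 0
    prev_total = None
    for pos, (key, (g, record)) in enumerate(items, start=1):
        if record.total != prev_total:
            rank = pos
            prev_total = record.total
        solutions.append(
            RankedSolution(rank, key, g, record, is_answer=(key == answer_key))
        )
    answer_rank = next((s.rank for s in solutions if s.is_answer), None)
    meta = {
        "runs": len(solution_sets),
        "seeds": [s.meta.get("seed") for s in solution_sets],
    }
    return SolutionSet(solutions, signature, answer_rank, meta)
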