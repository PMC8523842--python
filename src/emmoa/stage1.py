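"""Stage 1: evolutionary multitasking over one population with two task
labels, producing a Pareto archive per task.

Each individual optimizes only the task named by its label: label-1
individuals are scored on (MAR, NC), label-2 on (SAR, NC). Labels are
inherited through variation, so the label mix drifts with selection;
mixed-label parent pairs are the conduit for cross-task transfer.
Termination is budget-driven: the stage stops once its evaluation allotment
is exhausted (finishing the current generation from cache only), or when no
new distinct evaluation has occurred for a configurable number of
generations, which signals a converged, fully-cached population.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .objectives import ObjectiveBackend
from .operators import EAConfig, make_offspring, rank_and_crowd, tournament_select
from .pareto import Individual, ParetoArchive, crowding_distance, non_dominated_sort

logger = logging.getLogger(__name__)


@dataclass
class GenerationRecord:
    generation: int
    evaluations: int
    ps_mi_size: int
    ps_ssvep_size: int
    best_mar: float
    best_sar: float


@dataclass
class Stage1Result:
    ps_mi: ParetoArchive
    ps_ssvep: ParetoArchive
    population: list[Individual]
    history: list[GenerationRecord] = field(default_factory=list)
    generations: int = 0


def initialize_population(config: EAConfig, rng: np.random.Generator
                          ) -> list[Individual]:
    """Uniform random masks (each bit set iff its U[0,1] draw exceeds 0.5)
    with task labels drawn uniformly from {1, 2}; objectives unevaluated."""
    draws = rng.uniform(size=(config.population_size, config.n_channels))
    labels = rng.integers(1, 3, size=config.population_size)
    return [Individual(mask=(row > 0.5).astype(np.uint8), task_label=int(lab))
            for row, lab in zip(draws, labels)]


def evaluate_individual(ind: Individual, backend: ObjectiveBackend) -> bool:
    """Score an individual on its own task; returns False when the budget
    blocked a fresh computation (objectives stay None)."""
    if ind.objectives is not None:
        return True
    acc = backend.task_accuracy(ind.mask, ind.task_label)
    if acc is None:
        return False
    ind.objectives = (acc, float(backend.nc(ind.mask)))
    return True


def environmental_selection(pool: Sequence[Individual], config: EAConfig,
                            rng: np.random.Generator) -> list[Individual]:
    """Select N survivors from parents + offspring.

    The pool is split by task label; each label group keeps a quota
    proportional to its share of the pool (rounded; quotas sum to N), and
    survivors within a group are chosen NSGA-II style: whole fronts by
    rank, the cut front by descending crowding distance. If one label has
    died out, all survivors come from the other group and multitasking has
    degenerated to a single-task search.
    """
    n = config.population_size
    groups = {1: [i for i, ind in enumerate(pool) if ind.task_label == 1],
              2: [i for i, ind in enumerate(pool) if ind.task_label == 2]}
    if len(pool) <= n:
        return list(pool)
    if not groups[1] or not groups[2]:
        warnings.warn("one task label has died out; multitasking degenerates "
                      "to a single-task search", RuntimeWarning)
    quota1 = int(round(n * len(groups[1]) / len(pool)))
    quota1 = min(max(quota1, n - len(groups[2])), len(groups[1]), n)
    quotas = {1: quota1, 2: n - quota1}

    survivors: list[Individual] = []
    for label, idx in groups.items():
        quota = quotas[label]
        if quota == 0 or not idx:
            continue
        objs = [pool[i].objectives for i in idx]
        if any(o is None for o in objs):
            raise ValueError("environmental selection requires evaluated individuals")
        ranks = np.asarray(non_dominated_sort(objs))
        chosen: list[int] = []
        for r in range(ranks.max() + 1):
            front = [k for k in range(len(idx)) if ranks[k] == r]
            if len(chosen) + len(front) <= quota:
                chosen.extend(front)
            else:
                need = quota - len(chosen)
                dist = crowding_distance([objs[k] for k in front])
                order = sorted(range(len(front)), key=lambda j: (-dist[j], front[j]))
                chosen.extend(front[j] for j in order[:need])
            if len(chosen) >= quota:
                break
        survivors.extend(pool[idx[k]] for k in chosen)
    return survivors


def run_stage1(backend: ObjectiveBackend, config: EAConfig,
               rng: np.random.Generator) -> Stage1Result:
    """Run the multitasking stage until its evaluation allotment is spent.

    Per generation: tournament selection, pairwise variation with label
    inheritance, evaluation of the offspring on their own tasks,
    environmental selection back to N, and archive updates (label-1
    survivors into the MI archive, label-2 into the SSVEP archive).
    """
    ps_mi = ParetoArchive(cap=config.archive_cap, objective_view="mi")
    ps_ssvep = ParetoArchive(cap=config.archive_cap, objective_view="ssvep")

    population = initialize_population(config, rng)
    budget_hit = False
    for ind in population:
        if not evaluate_individual(ind, backend):
            budget_hit = True
    population = [ind for ind in population if ind.objectives is not None]
    if not population:
        return Stage1Result(ps_mi=ps_mi, ps_ssvep=ps_ssvep, population=[])

    ps_mi.update(ind.copy() for ind in population if ind.task_label == 1)
    ps_ssvep.update(ind.copy() for ind in population if ind.task_label == 2)

    result = Stage1Result(ps_mi=ps_mi, ps_ssvep=ps_ssvep, population=population)
    gen = 0
    stall = 0
    while not budget_hit and backend.ledger.can_spend():
        gen += 1
        count_before = backend.ledger.count
        parents = tournament_select(population, rng)
        offspring = make_offspring(parents, config, rng)
        for child in offspring:
            if not evaluate_individual(child, backend):
                budget_hit = True
        offspring = [c for c in offspring if c.objectives is not None]
        pool = population + offspring
        population = environmental_selection(pool, config, rng)
        ps_mi.update(ind.copy() for ind in population if ind.task_label == 1)
        ps_ssvep.update(ind.copy() for ind in population if ind.task_label == 2)

        result.history.append(GenerationRecord(
            generation=gen,
            evaluations=backend.ledger.count,
            ps_mi_size=len(ps_mi),
            ps_ssvep_size=len(ps_ssvep),
            best_mar=ps_mi.best(0),
            best_sar=ps_ssvep.best(0),
        ))
        logger.info("gen %d: evals=%d |PS_MI|=%d |PS_SSVEP|=%d best MAR=%.4f "
                    "best SAR=%.4f", gen, backend.ledger.count, len(ps_mi),
                    len(ps_ssvep), ps_mi.best(0), ps_ssvep.best(0))

        if backend.ledger.count == count_before:
            stall += 1
            if stall >= config.stall_generations:
                logger.info("stopping: %d generations without a new distinct "
                            "evaluation", stall)
                break
        else:
            stall = 0
    result.population = population
    result.generations = gen
    return result
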