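"""Variation operators on binary channel masks, and the run configuration.

The crossover is a two-point segment exchange: on binary strings the
positional partially-mapped crossover has no permutation structure to
repair, so exchanging the segment between two uniformly drawn cut points is
exactly what it reduces to. Mutation is independent per-bit flipping.
Tournament selection compares individuals NSGA-II style — non-domination
rank within the individual's own task view first, crowding distance second,
a seeded coin last.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .pareto import Individual, crowding_distance, non_dominated_sort


@dataclass
class EAConfig:
    """Run configuration for the two-stage channel-selection search.

    Defaults: population 100, crossover probability 0.8, mutation
    probability 0.2 (the per-pair trigger; the per-bit flip rate defaults to
    1/K), a total budget of 10000 objective evaluations with 90% spent in
    the multitasking stage, and archives capped at 100 members.

    mi_block / ssvep_block are 1-based inclusive channel ranges (the
    user-facing convention); the *_indices properties expose them 0-based.
    """

    n_channels: int = 15
    population_size: int = 100
    crossover_probability: float = 0.8
    mutation_probability: float = 0.2
    bit_flip_rate: Optional[float] = None  # None -> 1 / n_channels
    evaluation_budget: int = 10000
    archive_cap: int = 100
    mi_block: tuple[int, int] = (1, 11)
    ssvep_block: tuple[int, int] = (12, 15)
    stage2_fraction: float = 0.1
    stage2_passes: int = 1
    stall_generations: int = 25
    cv_folds: int = 5
    cv_seed: int = 0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError("population_size must be even and >= 2")
        for name in ("crossover_probability", "mutation_probability"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.bit_flip_rate is not None and not 0.0 <= self.bit_flip_rate <= 1.0:
            raise ValueError("bit_flip_rate must be in [0, 1]")
        if self.evaluation_budget <= 0:
            raise ValueError("evaluation_budget must be positive")
        if not 0.0 <= self.stage2_fraction < 1.0:
            raise ValueError("stage2_fraction must be in [0, 1)")
        lo1, hi1 = self.mi_block
        lo2, hi2 = self.ssvep_block
        if not (lo1 == 1 and hi1 + 1 == lo2 and hi2 == self.n_channels and lo1 <= hi1 <= hi2):
            raise ValueError(
                f"blocks {self.mi_block} and {self.ssvep_block} must partition "
                f"1..{self.n_channels}"
            )

    @property
    def flip_rate(self) -> float:
        return self.bit_flip_rate if self.bit_flip_rate is not None else 1.0 / self.n_channels

    @property
    def mi_block_indices(self) -> tuple[int, ...]:
        return tuple(range(self.mi_block[0] - 1, self.mi_block[1]))

    @property
    def ssvep_block_indices(self) -> tuple[int, ...]:
        return tuple(range(self.ssvep_block[0] - 1, self.ssvep_block[1]))

    @property
    def stage1_budget(self) -> int:
        return int(round(self.evaluation_budget * (1.0 - self.stage2_fraction)))


def rank_and_crowd(population: Sequence[Individual]) -> dict[int, tuple[int, float]]:
    """Per-individual (non-domination rank, crowding distance), computed
    within the individual's own task-label group under its 2-objective view.

    Returns a dict keyed by position in `population`.
    """
    out: dict[int, tuple[int, float]] = {}
    for label in (1, 2):
        idx = [i for i, ind in enumerate(population) if ind.task_label == label]
        if not idx:
            continue
        objs = [population[i].objectives for i in idx]
        if any(o is None for o in objs):
            raise ValueError("all individuals must be evaluated before selection")
        ranks = non_dominated_sort(objs)
        by_rank: dict[int, list[int]] = {}
        for local, r in enumerate(ranks):
            by_rank.setdefault(r, []).append(local)
        crowd = np.zeros(len(idx))
        for members in by_rank.values():
            d = crowding_distance([objs[m] for m in members])
            for m, dm in zip(members, d):
                crowd[m] = dm
        for local, i in enumerate(idx):
            out[i] = (ranks[local], float(crowd[local]))
    return out


def tournament_select(population: Sequence[Individual],
                      rng: np.random.Generator) -> list[Individual]:
    """Binary tournament selection with replacement; returns len(population)
    parents. Lower rank wins, then larger crowding distance, then a coin."""
    scores = rank_and_crowd(population)
    n = len(population)
    parents: list[Individual] = []
    for _ in range(n):
        i, j = rng.integers(0, n, size=2)
        ri, ci = scores[int(i)]
        rj, cj = scores[int(j)]
        if ri != rj:
            winner = i if ri < rj else j
        elif ci != cj:
            winner = i if ci > cj else j
        else:
            winner = i if rng.random() < 0.5 else j
        parents.append(population[int(winner)])
    return parents


def crossover_masks(p1: np.ndarray, p2: np.ndarray,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two-point segment exchange between equal-length binary masks.

    Cut points are drawn uniformly from 0..K; the slice between them is
    swapped, so child1[i] + child2[i] == p1[i] + p2[i] at every position.
    """
    p1 = np.asarray(p1, dtype=np.uint8)
    p2 = np.asarray(p2, dtype=np.uint8)
    if p1.shape != p2.shape:
        raise ValueError("parent masks must have equal length")
    k = len(p1)
    a, b = sorted(int(c) for c in rng.integers(0, k + 1, size=2))
    c1, c2 = p1.copy(), p2.copy()
    c1[a:b], c2[a:b] = p2[a:b].copy(), p1[a:b].copy()
    return c1, c2


def flip_bit_mutation(mask: np.ndarray, per_bit_rate: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Flip each bit independently with probability per_bit_rate."""
    if not 0.0 <= per_bit_rate <= 1.0:
        raise ValueError(f"per_bit_rate must be in [0, 1], got {per_bit_rate}")
    mask = np.asarray(mask, dtype=np.uint8)
    flips = rng.random(len(mask)) < per_bit_rate
    out = mask.copy()
    out[flips] ^= 1
    return out


def make_offspring(parents: Sequence[Individual], config: EAConfig,
                   rng: np.random.Generator) -> list[Individual]:
    """Pair consecutive parents and produce offspring with inherited labels.

    Same-label pairs always recombine. Mixed-label pairs recombine with
    probability pc; failing that they mutate (both parents, per-bit flips)
    with probability pm; failing both they are copied through unchanged.
    Each offspring inherits the task label of its positional parent. An odd
    trailing parent is copied through.
    """
    offspring: list[Individual] = []
    n = len(parents)
    for i in range(0, n - 1, 2):
        p1, p2 = parents[i], parents[i + 1]
        if p1.task_label == p2.task_label:
            m1, m2 = crossover_masks(p1.mask, p2.mask, rng)
        else:
            if rng.random() < config.crossover_probability:
                m1, m2 = crossover_masks(p1.mask, p2.mask, rng)
            elif rng.random() < config.mutation_probability:
                m1 = flip_bit_mutation(p1.mask, config.flip_rate, rng)
                m2 = flip_bit_mutation(p2.mask, config.flip_rate, rng)
            else:
                m1, m2 = p1.mask.copy(), p2.mask.copy()
        offspring.append(Individual(mask=m1, task_label=p1.task_label))
        offspring.append(Individual(mask=m2, task_label=p2.task_label))
    if n % 2:
        offspring.append(parents[-1].copy(objectives=None))
    return offspring
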