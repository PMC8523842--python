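"""Pareto dominance, non-dominated sorting, crowding distance, capped archives.

All objectives are maximized. A solution dominates another when it is at
least as good in every objective and strictly better in at least one.
Archives are truncated to their cap by iteratively dropping the member with
the smallest crowding distance (recomputed after each removal), so the
per-objective extreme points — which carry infinite distance — always
survive.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

_order_counter = itertools.count()


@dataclass
class Individual:
    """A candidate channel subset with its task assignment.

    mask is a binary vector over the montage (1 = channel selected).
    task_label is 1 for the motor-imagery task, 2 for the SSVEP task.
    objectives caches the maximized objective tuple once evaluated:
    (accuracy, NC) during the two-objective stage, (MAR, SAR, NC) in the
    final three-objective set.
    """

    mask: np.ndarray
    task_label: int
    objectives: Optional[tuple[float, ...]] = None
    _order: int = field(default_factory=lambda: next(_order_counter), repr=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.mask.ndim != 1 or not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be a 1-D binary vector")
        if self.task_label not in (1, 2):
            raise ValueError(f"task_label must be 1 or 2, got {self.task_label}")

    def key(self) -> bytes:
        """Hashable identity of the channel subset."""
        return self.mask.tobytes()

    def copy(self, *, task_label: Optional[int] = None,
             objectives: object = "keep") -> "Individual":
        return Individual(
            mask=self.mask.copy(),
            task_label=self.task_label if task_label is None else task_label,
            objectives=self.objectives if objectives == "keep" else objectives,
        )

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


def dominates(a: Sequence[float], b: Sequence[float]) -> bool:
    """True iff `a` Pareto-dominates `b` under maximization."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"objective dimension mismatch: {a.shape} vs {b.shape}")
    return bool(np.all(a >= b) and np.any(a > b))


def non_dominated_filter(points: Sequence[Sequence[float]]) -> list[int]:
    """Indices of the points not dominated by any other point.

    Objective-space duplicates never dominate each other, so all copies are
    retained.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n == 0:
        return []
    keep = []
    for i in range(n):
        ge = np.all(pts >= pts[i], axis=1)
        gt = np.any(pts > pts[i], axis=1)
        if not np.any(ge & gt):
            keep.append(i)
    return keep


def non_dominated_sort(points: Sequence[Sequence[float]]) -> list[int]:
    """Rank of each point: 0 for the first non-dominated front, 1 for the
    front obtained after removing front 0, and so on."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    ranks = np.full(n, -1, dtype=int)
    remaining = list(range(n))
    rank = 0
    while remaining:
        sub = pts[remaining]
        front_local = non_dominated_filter(sub)
        for j in front_local:
            ranks[remaining[j]] = rank
        remaining = [idx for k, idx in enumerate(remaining) if k not in set(front_local)]
        rank += 1
    return list(ranks)


def crowding_distance(front: Sequence[Sequence[float]]) -> np.ndarray:
    """Crowding distance of each member of a front.

    Per-objective boundary members get infinite distance; interior members
    accumulate (neighbour gap) / (objective range) per objective. An
    objective with zero range contributes nothing. Fronts of size <= 2 are
    all-infinite.
    """
    pts = np.asarray(front, dtype=float)
    n = len(pts)
    if n == 0:
        return np.empty(0)
    if n <= 2:
        return np.full(n, np.inf)
    dist = np.zeros(n)
    for m in range(pts.shape[1]):
        order = np.argsort(pts[:, m], kind="stable")
        vals = pts[order, m]
        rng = vals[-1] - vals[0]
        dist[order[0]] = np.inf
        dist[order[-1]] = np.inf
        if rng > 0:
            gaps = (vals[2:] - vals[:-2]) / rng
            dist[order[1:-1]] += gaps
    return dist


class ParetoArchive:
    """A capped set of mutually non-dominated individuals.

    objective_view names what the objective tuple means ("mi" -> (MAR, NC),
    "ssvep" -> (SAR, NC), "final" -> (MAR, SAR, NC)); it is descriptive
    metadata, not behaviour. Two members never share the same channel mask;
    distinct masks with identical objective vectors are all retained.
    """

    def __init__(self, cap: int = 100, objective_view: str = "mi") -> None:
        if cap < 1:
            raise ValueError("archive cap must be >= 1")
        self.cap = cap
        self.objective_view = objective_view
        self.members: list[Individual] = []

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def objective_matrix(self) -> np.ndarray:
        return np.asarray([m.objectives for m in self.members], dtype=float)

    def update(self, candidates: Iterable[Individual]) -> "ParetoArchive":
        """Merge candidates, keep the non-dominated set, truncate to cap.

        Candidates must be evaluated. Truncation repeatedly removes the
        member with the smallest crowding distance, recomputing distances
        after each removal; among tied minima the latest-inserted member is
        removed, so the earliest insertion survives.
        """
        pool: list[Individual] = list(self.members)
        seen = {m.key() for m in pool}
        for c in candidates:
            if c.objectives is None:
                raise ValueError("archive candidates must carry objective values")
            if c.key() in seen:
                continue
            seen.add(c.key())
            pool.append(c)
        if not pool:
            self.members = []
            return self
        keep = non_dominated_filter([m.objectives for m in pool])
        front = [pool[i] for i in keep]
        while len(front) > self.cap:
            dist = crowding_distance([m.objectives for m in front])
            worst = np.min(dist)
            tied = [i for i, d in enumerate(dist) if d == worst]
            victim = max(tied, key=lambda i: front[i]._order)
            front.pop(victim)
        self.members = front
        return self

    def best(self, objective_index: int) -> float:
        """Largest value of one objective across members (-inf if empty)."""
        if not self.members:
            return float("-inf")
        return float(self.objective_matrix()[:, objective_index].max())
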