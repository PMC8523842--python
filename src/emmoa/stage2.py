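"""Stage 2: decision-variable analysis and guided local search, producing
the final three-objective (MAR, SAR, NC) Pareto set.

Decision-variable analysis votes channel by channel: for each archive
member, toggling the channel's bit on (or off) and observing whether the
task accuracy rises or falls casts a +1 or -1 vote for the channel being
profitable. The sign of the tally assigns each channel to the add, delete
or invalid group. The motor-block channels are judged by the MI archive
under MAR, the occipital-block channels by the SSVEP archive under SAR.
Local search then nudges each archive member by one randomly chosen channel
of the *other* task's block, in the direction the groups indicate, and the
final set is the capped non-dominated filter of everything under the full
three-objective view.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .objectives import ObjectiveBackend
from .operators import EAConfig
from .pareto import Individual, ParetoArchive

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariableGroups:
    """Partition of channel indices (0-based) into search directions."""

    add_group: frozenset[int]
    delete_group: frozenset[int]
    invalid_group: frozenset[int]

    def __post_init__(self) -> None:
        groups = (self.add_group, self.delete_group, self.invalid_group)
        total = sum(len(g) for g in groups)
        if total != len(self.add_group | self.delete_group | self.invalid_group):
            raise ValueError("add/delete/invalid groups must be disjoint")

    def merged(self, other: "VariableGroups") -> "VariableGroups":
        return VariableGroups(
            add_group=self.add_group | other.add_group,
            delete_group=self.delete_group | other.delete_group,
            invalid_group=self.invalid_group | other.invalid_group,
        )

    def report(self) -> dict:
        """1-based channel indices per group, for user-facing output."""
        return {
            "add_group": sorted(i + 1 for i in self.add_group),
            "delete_group": sorted(i + 1 for i in self.delete_group),
            "invalid_group": sorted(i + 1 for i in self.invalid_group),
        }


def analyze_block(archive: Sequence[Individual], block: Sequence[int],
                  accuracy_fn: Callable[[np.ndarray], Optional[float]]
                  ) -> VariableGroups:
    """Vote each channel of `block` into add/delete/invalid over an archive.

    For member x and channel j: toggling j from 0 to 1 votes +1 if accuracy
    rises and -1 if it falls; toggling 1 to 0 votes -1 if accuracy rises
    and +1 if it falls; unchanged accuracy casts no vote. accuracy_fn must
    be the task accuracy matching the archive; the baseline is the member's
    cached accuracy when available. A None from accuracy_fn (budget
    exhausted) casts no vote.
    """
    add, delete, invalid = set(), set(), set()
    if not archive:
        warnings.warn("empty archive: all analyzed channels marked invalid",
                      RuntimeWarning)
        return VariableGroups(frozenset(), frozenset(), frozenset(block))
    for j in block:
        flag = 0
        for member in archive:
            base = (member.objectives[0] if member.objectives is not None
                    else accuracy_fn(member.mask))
            if base is None:
                continue
            toggled = member.mask.copy()
            toggled[j] ^= 1
            acc = accuracy_fn(toggled)
            if acc is None:
                continue
            if member.mask[j] == 0:  # toggled 0 -> 1
                flag += (acc > base) - (acc < base)
            else:  # toggled 1 -> 0: better without the channel means delete
                flag += (acc < base) - (acc > base)
        (add if flag > 0 else delete if flag < 0 else invalid).add(j)
    return VariableGroups(frozenset(add), frozenset(delete), frozenset(invalid))


def decision_variable_analysis(ps_mi: ParetoArchive, ps_ssvep: ParetoArchive,
                               backend: ObjectiveBackend, config: EAConfig
                               ) -> VariableGroups:
    """Classify every channel: the motor block over the MI archive with MAR,
    the occipital block over the SSVEP archive with SAR."""
    mi_groups = analyze_block(list(ps_mi), config.mi_block_indices, backend.mar)
    ssvep_groups = analyze_block(list(ps_ssvep), config.ssvep_block_indices,
                                 backend.sar)
    groups = mi_groups.merged(ssvep_groups)
    logger.info("variable groups: %s", groups.report())
    return groups


def local_search(ps_mi: ParetoArchive, ps_ssvep: ParetoArchive,
                 groups: VariableGroups, config: EAConfig,
                 rng: np.random.Generator) -> list[Individual]:
    """One guided toggle per archive member, in the other task's block.

    For an MI-archive member, a channel r is drawn uniformly from the
    occipital block; if r is in the add group and unset it is set, if in
    the delete group and set it is cleared. Symmetrically for SSVEP-archive
    members with r drawn from the motor block. The (possibly unchanged)
    copy joins the candidate list, so there is exactly one candidate per
    member.
    """
    candidates: list[Individual] = []
    for archive, block in ((ps_mi, config.ssvep_block_indices),
                           (ps_ssvep, config.mi_block_indices)):
        for member in archive:
            r = int(rng.choice(block))
            mask = member.mask.copy()
            if r in groups.add_group and mask[r] == 0:
                mask[r] = 1
            elif r in groups.delete_group and mask[r] == 1:
                mask[r] = 0
            candidates.append(Individual(mask=mask, task_label=member.task_label))
    return candidates


def assemble_final_ps(ps_mi: ParetoArchive, ps_ssvep: ParetoArchive,
                      candidates: Sequence[Individual],
                      backend: ObjectiveBackend, cap: int) -> ParetoArchive:
    """Non-dominated filter of archives + candidates under (MAR, SAR, NC).

    Every solution now needs both task accuracies; solutions that cannot be
    completed within the remaining budget are dropped with a warning.
    """
    pool: dict[bytes, Individual] = {}
    for ind in list(ps_mi) + list(ps_ssvep) + list(candidates):
        pool.setdefault(ind.key(), ind)
    evaluated: list[Individual] = []
    dropped = 0
    for ind in pool.values():
        mar = backend.mar(ind.mask)
        sar = backend.sar(ind.mask)
        if mar is None or sar is None:
            dropped += 1
            continue
        evaluated.append(Individual(
            mask=ind.mask.copy(), task_label=ind.task_label,
            objectives=(mar, sar, float(backend.nc(ind.mask)))))
    if dropped:
        warnings.warn(f"budget exhausted: {dropped} solutions lacked a "
                      "cross-task accuracy and were dropped from the final set",
                      RuntimeWarning)
    final = ParetoArchive(cap=cap, objective_view="final")
    final.update(evaluated)
    return final


@dataclass
class Stage2Result:
    final_ps: ParetoArchive
    groups: VariableGroups
    candidates: int


def run_stage2(ps_mi: ParetoArchive, ps_ssvep: ParetoArchive,
               backend: ObjectiveBackend, config: EAConfig,
               rng: np.random.Generator) -> Stage2Result:
    """Run the configured number of analysis + local-search passes and
    assemble the final three-objective Pareto set."""
    all_candidates: list[Individual] = []
    groups = VariableGroups(frozenset(), frozenset(),
                            frozenset(range(config.n_channels)))
    for _ in range(max(1, config.stage2_passes)):
        groups = decision_variable_analysis(ps_mi, ps_ssvep, backend, config)
        all_candidates.extend(local_search(ps_mi, ps_ssvep, groups, config, rng))
    final = assemble_final_ps(ps_mi, ps_ssvep, all_candidates, backend,
                              cap=config.archive_cap)
    return Stage2Result(final_ps=final, groups=groups,
                        candidates=len(all_candidates))
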