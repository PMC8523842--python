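"""Decision-variable analysis, guided local search, final Pareto assembly."""
import numpy as np
import pytest

from emmoa.objectives import EvaluationLedger, ObjectiveBackend
from emmoa.operators import EAConfig
from emmoa.pareto import Individual, ParetoArchive
from emmoa.stage2 import (VariableGroups, analyze_block, assemble_final_ps,
                          local_search, run_stage2)

from conftest import brute_force_non_dominated


def make_member(mask, acc, label=1):
    mask = np.asarray(mask, dtype=np.uint8)
    return Individual(mask=mask, task_label=label,
                      objectives=(acc, float(len(mask) - mask.sum())))


def linear_accuracy(weights):
    """Deterministic accuracy model: 0.5 + w . mask."""
    w = np.asarray(weights, dtype=float)

    def fn(mask):
        return 0.5 + float(w @ np.asarray(mask, dtype=float))

    return fn


class TestAnalyzeBlock:
    def test_universally_helpful_channel_lands_in_add_group(self):
        fn = linear_accuracy([0.2, 0.0, 0.0, 0.0])
        members = [make_member(m, fn(m)) for m in
                   ([0, 1, 0, 0], [0, 0, 1, 1], [1, 1, 1, 0])]
        groups = analyze_block(members, range(4), fn)
        assert 0 in groups.add_group

    def test_irrelevant_channel_lands_in_invalid_group(self):
        fn = linear_accuracy([0.2, 0.0, -0.1, 0.0])
        members = [make_member(m, fn(m)) for m in
                   ([0, 1, 0, 0], [1, 0, 1, 0], [1, 1, 0, 1])]
        groups = analyze_block(members, range(4), fn)
        assert {1, 3} <= groups.invalid_group
        assert 2 in groups.delete_group

    def test_matches_exhaustive_toggle_enumeration(self):
        """Independent oracle: re-enumerate every member x channel toggle of a
        lookup-table accuracy model and tally votes by hand."""
        rng = np.random.default_rng(0)
        table = {tuple(bits): float(rng.random())
                 for bits in np.ndindex(2, 2, 2, 2)}

        def fn(mask):
            return table[tuple(int(b) for b in mask)]

        masks = [[0, 1, 0, 0], [1, 0, 1, 1], [0, 0, 1, 0]]
        members = [make_member(m, fn(m)) for m in masks]
        groups = analyze_block(members, range(4), fn)

        expected_add, expected_delete, expected_invalid = set(), set(), set()
        for j in range(4):
            flag = 0
            for m in masks:
                base = fn(m)
                toggled = list(m)
                toggled[j] ^= 1
                acc = fn(toggled)
                if m[j] == 0:
                    flag += 1 if acc > base else (-1 if acc < base else 0)
                else:
                    flag += 1 if acc < base else (-1 if acc > base else 0)
            (expected_add if flag > 0 else
             expected_delete if flag < 0 else expected_invalid).add(j)
        assert groups.add_group == expected_add
        assert groups.delete_group == expected_delete
        assert groups.invalid_group == expected_invalid

    def test_empty_archive_marks_block_invalid_with_warning(self):
        with pytest.warns(RuntimeWarning, match="empty archive"):
            groups = analyze_block([], range(3), linear_accuracy([0, 0, 0]))
        assert groups.invalid_group == {0, 1, 2}

    def test_groups_partition_block(self):
        fn = linear_accuracy([0.1, -0.1, 0.0, 0.05])
        members = [make_member([1, 0, 1, 0], fn([1, 0, 1, 0]))]
        groups = analyze_block(members, range(4), fn)
        union = groups.add_group | groups.delete_group | groups.invalid_group
        assert union == {0, 1, 2, 3}
        assert (len(groups.add_group) + len(groups.delete_group)
                + len(groups.invalid_group)) == 4


def _archive(members, view):
    archive = ParetoArchive(cap=100, objective_view=view)
    archive.members = list(members)
    return archive


class TestLocalSearch:
    def setup_method(self):
        self.cfg = EAConfig()

    def _mi_member(self, mask):
        return make_member(mask, 0.8, label=1)

    def test_all_invalid_groups_copy_members(self):
        groups = VariableGroups(frozenset(), frozenset(), frozenset(range(15)))
        mi = _archive([self._mi_member([1] * 11 + [0] * 4)], "mi")
        ssvep = _archive([make_member([0] * 11 + [1] * 4, 0.9, label=2)], "ssvep")
        out = local_search(mi, ssvep, groups, self.cfg, np.random.default_rng(0))
        assert len(out) == 2
        np.testing.assert_array_equal(out[0].mask, mi.members[0].mask)
        np.testing.assert_array_equal(out[1].mask, ssvep.members[0].mask)

    def test_mi_member_gains_exactly_one_occipital_channel(self):
        groups = VariableGroups(frozenset({11, 12, 13, 14}), frozenset(),
                                frozenset(range(11)))
        member = self._mi_member([1, 1, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        mi = _archive([member], "mi")
        ssvep = _archive([], "ssvep")
        for seed in range(10):
            out = local_search(mi, ssvep, groups, self.cfg,
                               np.random.default_rng(seed))
            added = out[0].mask.astype(int) - member.mask.astype(int)
            assert added.sum() == 1
            assert np.flatnonzero(added)[0] >= 11

    def test_delete_group_clears_set_bits_only(self):
        groups = VariableGroups(frozenset(), frozenset({11, 12, 13, 14}),
                                frozenset(range(11)))
        member = self._mi_member([1] * 15)
        out = local_search(_archive([member], "mi"), _archive([], "ssvep"),
                           groups, self.cfg, np.random.default_rng(1))
        removed = member.mask.astype(int) - out[0].mask.astype(int)
        assert removed.sum() == 1 and np.flatnonzero(removed)[0] >= 11

    def test_candidate_count_is_n1_plus_n2(self):
        rng = np.random.default_rng(2)
        mi = _archive([self._mi_member((rng.random(15) > 0.5).astype(int))
                       for _ in range(7)], "mi")
        ssvep = _archive([make_member((rng.random(15) > 0.5).astype(int), 0.5, 2)
                          for _ in range(4)], "ssvep")
        groups = VariableGroups(frozenset({0, 11}), frozenset({1, 12}),
                                frozenset(range(15)) - {0, 1, 11, 12})
        assert len(local_search(mi, ssvep, groups, self.cfg, rng)) == 11


class TestAssembleFinal:
    def test_three_objective_filter_matches_oracle(self, make_backend):
        backend = make_backend()
        rng = np.random.default_rng(0)
        members = []
        for _ in range(12):
            mask = (rng.random(15) > 0.6).astype(np.uint8)
            if mask.sum() == 0:
                mask[0] = 1
            members.append(Individual(mask=mask, task_label=1))
        mi = _archive(members[:6], "mi")
        for m in mi:
            m.objectives = (backend.mar(m.mask), float(backend.nc(m.mask)))
        ssvep = _archive([], "ssvep")
        final = assemble_final_ps(mi, ssvep, members[6:], backend, cap=100)

        pool = {}
        for m in members:
            pool[m.key()] = (backend.mar(m.mask), backend.sar(m.mask),
                             float(backend.nc(m.mask)))
        expected = {tuple(v) for i, v in enumerate(pool.values())
                    if i in brute_force_non_dominated(list(pool.values()))}
        got = {tuple(m.objectives) for m in final}
        assert got == expected

    def test_final_nc_consistent_with_popcount(self, make_backend):
        backend = make_backend()
        rng = np.random.default_rng(1)
        members = [Individual(mask=(rng.random(15) > 0.5).astype(np.uint8),
                              task_label=2) for _ in range(5)]
        final = assemble_final_ps(_archive([], "mi"), _archive([], "ssvep"),
                                  members, backend, cap=100)
        for m in final:
            assert m.objectives[2] == 15 - m.mask.sum()

    def test_dominant_solution_is_sole_member(self, make_backend):
        backend = make_backend()

        class Stub:
            def __init__(self, table):
                self.table = table
                self.nc = backend.nc

            def mar(self, mask):
                return self.table[np.asarray(mask).tobytes()][0]

            def sar(self, mask):
                return self.table[np.asarray(mask).tobytes()][1]

        rng = np.random.default_rng(2)
        masks = [(rng.random(15) > 0.5).astype(np.uint8) for _ in range(4)]
        best = np.zeros(15, dtype=np.uint8)
        best[0] = 1
        table = {m.tobytes(): (0.5, 0.5) for m in masks}
        table[best.tobytes()] = (1.0, 1.0)  # best MAR, SAR, and NC at once
        stub = Stub(table)
        candidates = [Individual(mask=m, task_label=1) for m in masks + [best]]
        final = assemble_final_ps(_archive([], "mi"), _archive([], "ssvep"),
                                  candidates, stub, cap=100)
        assert len(final) == 1
        np.testing.assert_array_equal(final.members[0].mask, best)

    def test_budget_exhaustion_drops_uncompletable_solutions(self, make_backend):
        backend = make_backend(budget=2)
        rng = np.random.default_rng(3)
        members = [Individual(mask=(rng.random(15) > 0.5).astype(np.uint8),
                              task_label=1) for _ in range(5)]
        with pytest.warns(RuntimeWarning, match="budget exhausted"):
            final = assemble_final_ps(_archive([], "mi"), _archive([], "ssvep"),
                                      members, backend, cap=100)
        assert len(final) <= 1  # only the first solution got both accuracies


class TestRunStage2:
    def test_stage2_preserves_three_objective_nondominated_archive_members(
            self, make_backend):
        """No solution from PS_MI or PS_SSVEP that is non-dominated under
        (MAR, SAR, NC) may be lost by the local-search stage."""
        backend = make_backend()
        cfg = EAConfig(population_size=10)
        rng = np.random.default_rng(4)
        mi_members, ssvep_members = [], []
        for _ in range(5):
            mask = (rng.random(15) > 0.5).astype(np.uint8)
            mask[0] = 1
            mi_members.append(Individual(
                mask=mask, task_label=1,
                objectives=(backend.mar(mask), float(backend.nc(mask)))))
            mask2 = (rng.random(15) > 0.5).astype(np.uint8)
            mask2[14] = 1
            ssvep_members.append(Individual(
                mask=mask2, task_label=2,
                objectives=(backend.sar(mask2), float(backend.nc(mask2)))))
        mi = _archive(mi_members, "mi")
        ssvep = _archive(ssvep_members, "ssvep")
        res = run_stage2(mi, ssvep, backend, cfg, rng)

        all_objs = []
        for m in mi_members + ssvep_members:
            all_objs.append((backend.mar(m.mask), backend.sar(m.mask),
                             float(backend.nc(m.mask))))
        final_keys = {m.key() for m in res.final_ps}
        nd = brute_force_non_dominated(all_objs)
        originals = mi_members + ssvep_members
        for i in nd:
            assert originals[i].key() in final_keys
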