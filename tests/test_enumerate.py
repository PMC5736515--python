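"""Breadth-first engine: expansion semantics, small alkane series, variants."""

import pytest

from rxnspace.chem import parse_molecule
from rxnspace.enumerate import (
    ConfigurationError,
    EnumerationState,
    augmentation_rules,
    canonical_augmentation,
    enumerate_isomers,
    enumerate_queue,
    expand_once,
)
from rxnspace.fixtures import free_tree_alkanes, linear_alkane

# (n_carbons, isomer count, printed iteration count) for the small series
ALKANE_SERIES = [(1, 1, 1), (2, 1, 1), (3, 1, 1), (4, 2, 2), (5, 3, 3),
                 (6, 5, 3), (7, 9, 4), (8, 18, 5)]


class TestExpandOnce:
    def test_augmentation_step_from_propane(self):
        state = EnumerationState.from_seeds([parse_molecule("CCC")])
        expand_once(state, augmentation_rules(1))
        assert {m.canonical_key for m in state.source} == {"CCCC", "CC(C)C"}
        assert state.iteration == 1
        assert set(state.sink) >= {m.canonical_key for m in state.source}

    def test_no_match_terminates(self, rule_r1):
        state = EnumerationState.from_seeds([parse_molecule("C", "explicit")])
        expand_once(state, [rule_r1])
        assert state.source == []

    def test_fixed_point_on_reexpansion(self, rule_r1):
        state = EnumerationState.from_seeds([parse_molecule("CCCC", "explicit")])
        expand_once(state, [rule_r1])
        first = set(state.sink)
        expand_once(state, [rule_r1])
        second = set(state.sink)
        # butane's two isomers close the space: nothing new appears
        assert first == second

    def test_empty_rule_list_rejected(self):
        state = EnumerationState.from_seeds([parse_molecule("CC")])
        with pytest.raises(ConfigurationError):
            expand_once(state, [])

    def test_sink_grows_monotonically_and_uniquely(self, rule_r1):
        state = EnumerationState.from_seeds([parse_molecule("CCCCC", "explicit")])
        sizes = [len(state.sink)]
        seen_before = set(state.sink)
        for _ in range(4):
            expand_once(state, [rule_r1])
            assert set(state.sink) >= seen_before
            seen_before = set(state.sink)
            sizes.append(len(state.sink))
        assert sizes == sorted(sizes)


class TestIsomerTransformation:
    @pytest.mark.parametrize("n,count,iters", ALKANE_SERIES)
    def test_alkane_series_counts_and_iterations(self, rule_r1, n, count, iters):
        res = enumerate_isomers(linear_alkane(n), [rule_r1])
        assert len(res.structures) == count
        assert res.n_iterations == iters

    def test_methane_is_its_own_closure(self, rule_r1):
        res = enumerate_isomers(linear_alkane(1), [rule_r1])
        assert {m.canonical_key for m in res.structures} == {"C"}
        assert res.last_new_iteration == 0

    def test_last_new_iteration_within_alkane_bound(self, rule_r1):
        for n in range(2, 9):
            res = enumerate_isomers(linear_alkane(n), [rule_r1])
            assert res.last_new_iteration <= n - 1

    def test_seed_must_pass_filters(self, rule_r1):
        with pytest.raises(ConfigurationError):
            enumerate_isomers(parse_molecule("C1=C=CC1"), [rule_r1])

    def test_nonpositive_max_iter_rejected(self, rule_r1):
        with pytest.raises(ConfigurationError):
            enumerate_isomers(linear_alkane(4), [rule_r1], max_iter=0)

    def test_result_invariant_to_seed_choice(self, rule_r1):
        # any isomer seeds the same closure
        a = enumerate_isomers(parse_molecule("CCCCC"), [rule_r1])
        b = enumerate_isomers(parse_molecule("CC(C)(C)C"), [rule_r1])
        assert {m.canonical_key for m in a.structures} == {
            m.canonical_key for m in b.structures
        }

    def test_result_invariant_to_rule_order(self, rules19):
        fwd = enumerate_isomers(parse_molecule("C=CCC"), rules19)
        rev = enumerate_isomers(parse_molecule("C=CCC"), list(reversed(rules19)))
        assert {m.canonical_key for m in fwd.structures} == {
            m.canonical_key for m in rev.structures
        }

    def test_matches_free_tree_oracle(self, rule_r1):
        # independent brute-force free-tree generation agrees for N <= 8
        for n in range(2, 9):
            res = enumerate_isomers(linear_alkane(n), [rule_r1])
            assert {m.canonical_key for m in res.structures} == free_tree_alkanes(n)


class TestCanonicalAugmentation:
    def test_single_atom(self):
        structures, per_size = canonical_augmentation(1)
        assert len(structures) == 1 and per_size[1] == 1

    def test_cumulative_count_small(self):
        structures, per_size = canonical_augmentation(4)
        assert {m.canonical_key for m in structures} == {
            "C", "CC", "CCC", "CCCC", "CC(C)C"
        }
        assert dict(per_size) == {1: 1, 2: 1, 3: 1, 4: 2}

    def test_acyclic_with_single_bond_rule(self):
        structures, _ = canonical_augmentation(7)
        assert all(m.rdmol.GetRingInfo().NumRings() == 0 for m in structures)

    def test_ring_rules_generate_triangle_free_cycles(self):
        # with the 2-bond attachment rule cycles appear, but never triangles
        structures, _ = canonical_augmentation(6, augmentation_rules(2))
        assert any(m.rdmol.GetRingInfo().NumRings() > 0 for m in structures)
        assert all(
            not any(a.IsInRingSize(3) for a in m.rdmol.GetAtoms()) for m in structures
        )

    def test_cross_algorithm_consistency_small(self, rule_r1):
        # cumulative augmentation count at N equals the sum of per-N
        # transformation counts
        _, per_size = canonical_augmentation(8)
        for n in range(1, 9):
            res = enumerate_isomers(linear_alkane(n), [rule_r1])
            assert per_size[n] == len(res.structures)


class TestQueueVariant:
    @pytest.mark.parametrize("chunk_size", [1, 2, 5, 20])
    def test_queue_equals_bfs_on_pentane_and_hexane(self, rule_r1, chunk_size):
        for n, count in ((5, 3), (6, 5)):
            got = enumerate_queue(linear_alkane(n), [rule_r1], chunk_size=chunk_size)
            assert len(got) == count
            bfs = enumerate_isomers(linear_alkane(n), [rule_r1]).structures
            assert {m.canonical_key for m in got} == {m.canonical_key for m in bfs}

    def test_chunk_larger_than_queue_is_plain_bfs(self, rule_r1):
        got = enumerate_queue(linear_alkane(5), [rule_r1], chunk_size=10_000)
        assert len(got) == 3

    def test_bad_chunk_size(self, rule_r1):
        with pytest.raises(ConfigurationError):
            enumerate_queue(linear_alkane(4), [rule_r1], chunk_size=0)
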