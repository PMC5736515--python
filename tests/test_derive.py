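"""The 81 -> 36 -> 27 -> 19 derivation, rule identity/reversal, distances."""

import itertools

import numpy as np
import pytest

from rxnspace.chem import parse_molecule
from rxnspace.derive import (
    BondConfiguration,
    apply_config,
    bond_order_distance,
    derive_configs,
    derive_rules,
    emit_smarts,
    enumerate_feasible_configs,
    greedy_transform,
    iteration_upper_bound,
    reduce_by_ring_constraint,
    reduce_by_symmetry,
    reduce_by_valence,
    reverse_rule,
    rules_are_identical,
)


class TestReductionChain:
    def test_cardinality_chain(self):
        c81 = enumerate_feasible_configs()
        c36 = reduce_by_symmetry(c81)
        c27 = reduce_by_valence(c36)
        c19 = reduce_by_ring_constraint(c27)
        assert (len(c81), len(c36), len(c27), len(c19)) == (81, 36, 27, 19)

    def test_inclusion_exclusion_bookkeeping(self):
        # 27 violate condition 1, 27 violate condition 2, 9 violate both
        c81 = enumerate_feasible_configs()
        bad1 = {c for c in c81 if c.a14 < c.a23}
        bad2 = {c for c in c81 if c.a12 < c.a34}
        assert (len(bad1), len(bad2), len(bad1 & bad2)) == (27, 27, 9)
        assert 81 - 27 - 27 + 9 == 36

    def test_all_single_bond_config_survives(self):
        assert BondConfiguration(a12=1, a23=0, a34=1, a14=0) in derive_configs()

    def test_zero_order_bond_cannot_be_deleted(self):
        assert all(c.a12 >= 1 and c.a34 >= 1 for c in enumerate_feasible_configs())

    def test_valence_five_config_removed(self):
        c27 = reduce_by_valence(reduce_by_symmetry(enumerate_feasible_configs()))
        assert BondConfiguration(a12=3, a23=0, a34=1, a14=2) not in c27

    def test_small_ring_reactant_config_removed(self):
        c19 = set(derive_configs())
        assert BondConfiguration(a12=2, a23=1, a34=1, a14=2) not in c19

    def test_transformation_balances_creation_and_deletion(self):
        # each rule lowers two bond orders by one and raises two by one
        for c in derive_configs():
            deltas = [b - a for a, b in zip(c.reactant_orders, c.product_orders)]
            assert sorted(deltas) == [-1, -1, 1, 1]


class TestRuleIdentity:
    def test_every_rule_identical_to_itself(self):
        for c in derive_configs():
            assert rules_are_identical(c, c)

    def test_pairwise_non_identical(self):
        for a, b in itertools.combinations(derive_configs(), 2):
            assert not rules_are_identical(a, b)

    def test_label_swap_identity(self):
        # swapping labels (1,2)<->(2,1) and (3,4)<->(4,3) relabels the same rule
        r1 = BondConfiguration(a12=1, a23=0, a34=1, a14=0)
        # same edges read through pi = (2,1,4,3): still deletes two singles,
        # creates the two opposite bonds
        assert rules_are_identical(r1, r1)

    def test_reversal_closed_and_involutive(self):
        rules = derive_rules()
        pairing = {r.rule_id: reverse_rule(r).rule_id for r in rules}
        ids = {r.rule_id for r in rules}
        assert set(pairing.values()) <= ids  # closed under reversal
        assert all(pairing[v] == k for k, v in pairing.items())  # involution
        fixed = sorted(k for k, v in pairing.items() if k == v)
        # three self-inverse rules and eight mutual-reverse pairs
        assert len(fixed) == 3 and (19 - 3) % 2 == 0

    def test_self_inverse_rules_conserve_bond_multiset(self):
        # the self-inverse rules are exactly those that move a bond without
        # interconverting single/double/triple bonds
        for r in derive_rules():
            self_inverse = reverse_rule(r).rule_id == r.rule_id
            multiset_kept = sorted(r.config.reactant_orders) == sorted(
                r.config.product_orders
            )
            assert self_inverse == multiset_kept

    def test_mutual_reverses_not_identical(self):
        rules = {r.rule_id: r for r in derive_rules()}
        for rid, rule in rules.items():
            rev = reverse_rule(rule)
            if rev.rule_id != rid:
                assert not rules_are_identical(rule, rev)


class TestEmission:
    def test_emitted_smarts_parse_and_carry_config(self):
        for rule in derive_rules():
            assert rule.rxn is not None
            assert rule.config in derive_configs()

    def test_triple_bond_free_subset_is_strict(self):
        all_rules = derive_rules()
        reduced = derive_rules(include_triple_bonds=False)
        assert {r.rule_id for r in reduced} < {r.rule_id for r in all_rules}
        assert all(not r.config.uses_triple_bond for r in reduced)

    def test_emit_rejects_foreign_config(self):
        with pytest.raises(ValueError):
            emit_smarts(BondConfiguration(a12=3, a23=0, a34=1, a14=2))

    def test_valence_conserved_atomwise_by_every_rule(self):
        # explicit-hydrogen graphs: total bond order of every atom unchanged
        for smi in ("CCCC", "CC=CC", "C#CCC", "C1CCC1"):
            mol = parse_molecule(smi, "explicit").rdmol
            before = sorted(
                sum(int(b.GetBondTypeAsDouble()) for b in a.GetBonds())
                for a in mol.GetAtoms()
            )
            for rule in derive_rules():
                for p in apply_config(rule.config, mol):
                    after = sorted(
                        sum(int(b.GetBondTypeAsDouble()) for b in a.GetBonds())
                        for a in p.GetAtoms()
                    )
                    assert after == before


class TestDistance:
    def test_distance_to_self_is_zero(self):
        A = np.array([[0, 1], [1, 0]])
        assert bond_order_distance(A, A).S == 0

    def test_butane_vs_isobutane_labeled_distance(self):
        # skeletons on shared carbon indexing: chain 0-1-2-3 vs star 1-(0,2,3);
        # bonds (2,3) vs (1,3) differ -> S = 2 by direct summation
        chain = np.zeros((4, 4), dtype=int)
        for i, j in ((0, 1), (1, 2), (2, 3)):
            chain[i, j] = chain[j, i] = 1
        star = np.zeros((4, 4), dtype=int)
        for i, j in ((0, 1), (1, 2), (1, 3)):
            star[i, j] = star[j, i] = 1
        assert bond_order_distance(chain, star).S == 2

    def test_distance_is_even_and_symmetric(self):
        # valence-conserving isomer pairs always sit at even distance
        from rxnspace.fixtures import enumerate_carbon_multigraphs, explicit_hydrogen_matrix

        graphs = enumerate_carbon_multigraphs(4)
        mats = [explicit_hydrogen_matrix(A) for A, _ in graphs if A.sum() // 2 == 4]
        for A, B in itertools.combinations(mats, 2):
            s_ab = bond_order_distance(A, B).S
            assert s_ab % 2 == 0
            assert s_ab == bond_order_distance(B, A).S
            assert s_ab > 0

    def test_mismatched_atom_sets_raise(self):
        a = parse_molecule("CC", "explicit")
        b = parse_molecule("CO", "explicit")
        with pytest.raises(ValueError):
            bond_order_distance(a, b)

    def test_greedy_steps_reduce_by_two_or_four(self):
        # chain -> star rearrangement on explicit-H graphs
        from rxnspace.fixtures import explicit_hydrogen_matrix

        chain = np.zeros((5, 5), dtype=int)
        for i in range(4):
            chain[i, i + 1] = chain[i + 1, i] = 1
        star = np.zeros((5, 5), dtype=int)
        for j in (0, 2, 3, 4):
            star[1, j] = star[j, 1] = 1
        A, B = explicit_hydrogen_matrix(chain), explicit_hydrogen_matrix(star)
        S = bond_order_distance(A, B).S
        steps = greedy_transform(A, B)
        assert 1 <= len(steps) <= S // 2
        for _, _, s_before, s_after in steps:
            assert s_before - s_after in (2, 4)


class TestIterationBound:
    @pytest.mark.parametrize(
        "n,mode,expected",
        [(2, "general", 1), (4, "general", 9), (10, "alkane", 9), (1, "alkane", 0)],
    )
    def test_bound_values(self, n, mode, expected):
        assert iteration_upper_bound(n, mode) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            iteration_upper_bound(0)
        with pytest.raises(ValueError):
            iteration_upper_bound(3, "weird")
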