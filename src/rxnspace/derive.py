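"""Derivation of the minimal isomer-transformation rule set.

A constitutional isomer of a hydrogen-saturated molecule can be reached by
repeatedly rearranging bonds among four atoms: delete the bonds 1-2 and 3-4
and create 1-4 and 2-3 (each change of order one), which conserves the total
bond order of every atom.  Writing a12, a23, a34, a14 for the initial orders
of the four changed bonds (the diagonals a13 and a24 are untouched and
unconstrained), solvability forces a12, a34 in {1,2,3} and a14, a23 in
{0,1,2}: 81 candidate configurations.  Symmetry (a14 >= a23, a12 >= a34),
the maximal valence of 4, and the exclusion of two double bonds on one atom
of a 3- or 4-membered ring reduce these to 36, 27 and finally 19 distinct
minimal transformation rules.

This module enumerates and filters the configurations, emits each survivor
as a reaction SMARTS (and as a fast direct bond-editing applier), tests rule
identity under label permutation, reverses rules, and provides the labeled
bond-order distance that bounds how many transformations separate two
isomers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
from rdkit import Chem

from .chem import BOND_TYPES, Molecule, ReactionRule

#: the four changed bonds, in cycle order 1-2-3-4-1 (0-based labels)
CYCLE_EDGES = ((0, 1), (1, 2), (2, 3), (0, 3))
#: the two fixed (unconstrained) diagonals
DIAGONAL_EDGES = ((0, 2), (1, 3))

ALL_PERMUTATIONS = list(itertools.permutations(range(4)))


class BondConfiguration(NamedTuple):
    """Initial orders of the four changed bonds of a minimal transformation.

    The forced transformation is ``b12 = a12 - 1, b23 = a23 + 1,
    b34 = a34 - 1, b14 = a14 + 1``; diagonals keep their order.
    """

    a12: int
    a23: int
    a34: int
    a14: int

    @property
    def b12(self) -> int:
        return self.a12 - 1

    @property
    def b23(self) -> int:
        return self.a23 + 1

    @property
    def b34(self) -> int:
        return self.a34 - 1

    @property
    def b14(self) -> int:
        return self.a14 + 1

    @property
    def reactant_orders(self) -> tuple:
        return (self.a12, self.a23, self.a34, self.a14)

    @property
    def product_orders(self) -> tuple:
        return (self.b12, self.b23, self.b34, self.b14)

    @property
    def uses_triple_bond(self) -> bool:
        return 3 in self.reactant_orders or 3 in self.product_orders

    def reverse(self) -> "BondConfiguration":
        """The configuration of the reverse transformation.

        Reading the product side as a new reactant and relabelling the cycle
        by one position restores the canonical delta pattern (-1, +1, -1, +1).
        """
        return BondConfiguration(
            a12=self.a23 + 1, a23=self.a34 - 1, a34=self.a14 + 1, a14=self.a12 - 1
        )


def enumerate_feasible_configs() -> set:
    """All 81 bond configurations for which the system is solvable."""
    return {
        BondConfiguration(a12, a23, a34, a14)
        for a12 in (1, 2, 3)
        for a34 in (1, 2, 3)
        for a14 in (0, 1, 2)
        for a23 in (0, 1, 2)
    }


def reduce_by_symmetry(configs: Iterable[BondConfiguration]) -> set:
    """Keep one representative per symmetry class: a14 >= a23 and a12 >= a34."""
    return {c for c in configs if c.a14 >= c.a23 and c.a12 >= c.a34}


def reduce_by_valence(configs: Iterable[BondConfiguration]) -> set:
    """Drop configurations where atom 1 would need valence 5 (a12=3, a14=2)."""
    return {c for c in configs if not (c.a12 == 3 and c.a14 == 2)}


def reduce_by_ring_constraint(configs: Iterable[BondConfiguration]) -> set:
    """Drop configurations invalid under the small-ring double-bond rule.

    Reactant side: a12 = a14 = 2 with a34 in {1,2} and a23 in {1,2} puts two
    double bonds on atom 1 inside a 3- or 4-ring.  Product side: a12 = 3,
    a14 = 1 with a34 in {2,3} and a23 in {0,1} produces the same motif.
    """
    out = set()
    for c in configs:
        reactant_bad = c.a12 == 2 and c.a14 == 2 and c.a34 in (1, 2) and c.a23 in (1, 2)
        product_bad = c.a12 == 3 and c.a14 == 1 and c.a34 in (2, 3) and c.a23 in (0, 1)
        if not (reactant_bad or product_bad):
            out.add(c)
    return out


def derive_configs() -> list:
    """The 19 minimal-transformation configurations in canonical order.

    Canonical order is lexicographic on (a12, a23, a34, a14); rule numbering
    R1..R19 follows this sort.
    """
    configs = reduce_by_ring_constraint(
        reduce_by_valence(reduce_by_symmetry(enumerate_feasible_configs()))
    )
    return sorted(configs)


# ---------------------------------------------------------------------------
# SMARTS emission
# ---------------------------------------------------------------------------

_BOND_SMARTS = {1: "-", 2: "=", 3: "#"}


def _side_to_smarts(orders: Sequence[int]) -> str:
    """SMARTS for four labeled any-atoms joined along the cycle 1-2-3-4-1.

    ``orders[i]`` is the order of cycle edge i; order 0 means no bond, which
    splits the pattern into dot-separated fragments.
    """
    atoms = [f"[*:{i + 1}]" for i in range(4)]
    present = [o > 0 for o in orders]
    if all(present):
        # full 4-ring: close between atom 4 and atom 1
        return (
            f"{atoms[0]}1{_BOND_SMARTS[orders[0]]}{atoms[1]}"
            f"{_BOND_SMARTS[orders[1]]}{atoms[2]}"
            f"{_BOND_SMARTS[orders[2]]}{atoms[3]}"
            f"{_BOND_SMARTS[orders[3]]}1"
        )
    # break the cycle at a missing edge and walk the remaining path(s)
    start = next(i for i in range(4) if not present[i])
    walk = [(start + 1 + k) % 4 for k in range(4)]  # atom labels in path order
    fragments = []
    current = [atoms[walk[0]]]
    for idx in range(3):
        edge = walk[idx]  # edge between walk[idx] and walk[idx + 1]
        if present[edge]:
            current.append(_BOND_SMARTS[orders[edge]] + atoms[walk[idx + 1]])
        else:
            fragments.append("".join(current))
            current = [atoms[walk[idx + 1]]]
    fragments.append("".join(current))
    return ".".join(fragments)


def emit_smarts(
    config: BondConfiguration, include_triple_bonds: bool = True
) -> ReactionRule:
    """Emit a 4-mapped-atom reaction SMARTS for one of the 19 configurations.

    The pattern is component-grouped so it embeds within a single molecule;
    diagonals are omitted (unconstrained at match time, preserved at product
    construction).  With ``include_triple_bonds=False`` a configuration that
    touches an order-3 bond raises :class:`ValueError`.
    """
    canonical = derive_configs()
    if config not in canonical:
        raise ValueError(f"{config} is not one of the 19 minimal transformations")
    if not include_triple_bonds and config.uses_triple_bond:
        raise ValueError(f"{config} involves a triple bond")
    rule_id = f"R{canonical.index(config) + 1}"
    smarts = (
        f"({_side_to_smarts(config.reactant_orders)})>>"
        f"({_side_to_smarts(config.product_orders)})"
    )
    return ReactionRule(rule_id=rule_id, smarts=smarts, config=config)


def derive_rules(include_triple_bonds: bool = True) -> list:
    """The minimal isomer-transformation rule set as executable rules.

    Returns all 19 rules, or the strict subset avoiding triple bonds when
    ``include_triple_bonds`` is false.
    """
    return [
        emit_smarts(c)
        for c in derive_configs()
        if include_triple_bonds or not c.uses_triple_bond
    ]


def bond_moving_rules() -> list:
    """The self-inverse rules that conserve the bond-order multiset.

    These move a bond of each order without interconverting single, double
    and triple bonds (hence never turn a multiple bond into a cycle); they
    are the subset used for similarity-preserving chemical-space screening.
    """
    return [
        emit_smarts(c)
        for c in derive_configs()
        if sorted(c.reactant_orders) == sorted(c.product_orders)
    ]


# ---------------------------------------------------------------------------
# Rule identity, symmetry, reversal
# ---------------------------------------------------------------------------


def _edge_data(config: BondConfiguration) -> dict:
    """Map unordered label pair -> (initial order, final order).

    Diagonals carry the symbolic marker ("*", "*") since any order from 0 to
    3 is allowed and preserved.
    """
    data = {}
    for (i, j), a, b in zip(CYCLE_EDGES, config.reactant_orders, config.product_orders):
        data[frozenset((i, j))] = (a, b)
    for i, j in DIAGONAL_EDGES:
        data[frozenset((i, j))] = ("*", "*")
    return data


def _as_config(rule) -> BondConfiguration:
    if isinstance(rule, BondConfiguration):
        return rule
    if isinstance(rule, ReactionRule) and isinstance(rule.config, BondConfiguration):
        return rule.config
    raise TypeError(f"not a 4-atom bond-rearrangement rule: {rule!r}")


def rules_are_identical(rule_a, rule_b) -> bool:
    """True iff a label permutation carries one rule's edges onto the other's."""
    da, db = _edge_data(_as_config(rule_a)), _edge_data(_as_config(rule_b))
    for perm in ALL_PERMUTATIONS:
        if all(
            db[frozenset((perm[i], perm[j]))] == val
            for (i, j), val in ((tuple(key), v) for key, v in da.items())
        ):
            return True
    return False


def config_symmetries(config: BondConfiguration) -> list:
    """Label permutations mapping the transformation onto itself."""
    data = _edge_data(config)
    syms = []
    for perm in ALL_PERMUTATIONS:
        if all(
            data[frozenset((perm[i], perm[j]))] == val
            for key, val in data.items()
            for i, j in [tuple(key)]
        ):
            syms.append(perm)
    return syms


def reverse_rule(rule) -> ReactionRule:
    """The reverse transformation, returned as its canonical rule.

    The 19-rule set is closed under reversal: the raw reversed configuration
    is always identical (under label permutation) to one of the canonical 19.
    """
    rev = _as_config(rule).reverse()
    for c in derive_configs():
        if rules_are_identical(rev, c):
            return emit_smarts(c)
    raise ValueError(f"reverse of {rule!r} not found in the canonical set")


def iteration_upper_bound(n_atoms: int, mode: str = "general") -> int:
    """Worst-case number of breadth-first iterations to reach any isomer.

    ``general``: floor(3(N^2 - N)/4), from the maximal labeled bond-order
    distance 3(N^2 - N)/2 and the minimal per-step decrease of 2.
    ``alkane``: N - 1, from the acyclic single-bond case.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    if mode == "general":
        return (3 * (n_atoms * n_atoms - n_atoms)) // 4
    if mode == "alkane":
        return n_atoms - 1
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Fast direct application of a configuration to an explicit-hydrogen graph
# ---------------------------------------------------------------------------


def apply_config(config: BondConfiguration, mol: Chem.Mol) -> list:
    """All distinct applications of ``config`` to an explicit-H RDKit mol.

    Enumerates ordered embeddings of the four labeled atoms onto graph atoms
    matching the required bond orders (order 0 = no bond), deduplicates
    embeddings equivalent under the configuration's own label symmetries, and
    returns raw edited copies (unsanitized, possibly disconnected).

    Exactly equivalent to applying the emitted reaction SMARTS followed by
    the radical/sanitization filter, but avoids the quadratic blow-up of
    generic substructure matching on large hydrogen-explicit graphs.
    """
    a12, a23, a34, a14 = config.reactant_orders
    if any(b.GetBondType() == Chem.BondType.AROMATIC for b in mol.GetBonds()):
        mol = Chem.Mol(mol)
        Chem.Kekulize(mol, clearAromaticFlags=True)
    order = {}
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        o = int(b.GetBondTypeAsDouble())
        order[(i, j)] = o
        order[(j, i)] = o
    bonds12 = [(i, j) for (i, j), o in order.items() if o == a12]
    bonds34 = [(i, j) for (i, j), o in order.items() if o == a34]
    syms = config_symmetries(config)
    seen = set()
    products = []
    for i, j in bonds12:
        for k, l in bonds34:
            if len({i, j, k, l}) < 4:
                continue
            if order.get((j, k), 0) != a23:
                continue
            if order.get((i, l), 0) != a14:
                continue
            atoms = (i, j, k, l)
            sig = min(tuple(atoms[p] for p in perm) for perm in syms)
            if sig in seen:
                continue
            seen.add(sig)
            rw = Chem.RWMol(mol)
            for x, y, old, new in (
                (i, j, a12, config.b12),
                (j, k, a23, config.b23),
                (k, l, a34, config.b34),
                (i, l, a14, config.b14),
            ):
                if old > 0:
                    rw.RemoveBond(x, y)
                if new > 0:
                    rw.AddBond(x, y, BOND_TYPES[new])
            products.append(rw.GetMol())
    return products


# ---------------------------------------------------------------------------
# Labeled bond-order distance and greedy transformation (convergence bound)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabeledGraphDistance:
    """Sum of absolute bond-order differences under a fixed atom indexing."""

    S: int

    def __int__(self) -> int:
        return self.S


def adjacency_matrix(mol: Molecule | Chem.Mol) -> np.ndarray:
    """Integer bond-order adjacency matrix over all atoms (hydrogens included)."""
    rd = mol.rdmol if isinstance(mol, Molecule) else mol
    n = rd.GetNumAtoms()
    A = np.zeros((n, n), dtype=int)
    for b in rd.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        A[i, j] = A[j, i] = int(b.GetBondTypeAsDouble())
    return A


def bond_order_distance(
    mol_a, mol_b, shared_indexing: Optional[Sequence[int]] = None
) -> LabeledGraphDistance:
    """Labeled distance S between two molecules on the same atom multiset.

    ``shared_indexing`` maps atom i of ``mol_a`` to atom shared_indexing[i]
    of ``mol_b`` (identity by default).  The distance is taken over the
    *fixed* indexing, not minimized over isomorphisms.
    """
    A = mol_a if isinstance(mol_a, np.ndarray) else adjacency_matrix(mol_a)
    B = mol_b if isinstance(mol_b, np.ndarray) else adjacency_matrix(mol_b)
    if shared_indexing is not None:
        idx = np.asarray(shared_indexing)
        B = B[np.ix_(idx, idx)]
    if A.shape != B.shape:
        raise ValueError("molecules do not share an atom indexing")
    if not isinstance(mol_a, np.ndarray) and not isinstance(mol_b, np.ndarray):
        ea = [a.GetSymbol() for a in (mol_a.rdmol if isinstance(mol_a, Molecule) else mol_a).GetAtoms()]
        eb = [a.GetSymbol() for a in (mol_b.rdmol if isinstance(mol_b, Molecule) else mol_b).GetAtoms()]
        if shared_indexing is not None:
            eb = [eb[i] for i in shared_indexing]
        if ea != eb:
            raise ValueError("mismatched atom multisets under the shared indexing")
    return LabeledGraphDistance(int(np.abs(A - B).sum()) // 2)


def _matrix_violates_ring_rule(A: np.ndarray) -> bool:
    """Abstract-graph version of the small-ring double-bond exclusion."""
    n = A.shape[0]
    adj = A > 0
    for v in range(n):
        if int((A[v] == 2).sum()) < 2:
            continue
        nbrs = np.flatnonzero(adj[v])
        for u, w in itertools.combinations(nbrs, 2):
            if adj[u, w]:  # 3-ring v-u-w
                return True
            # 4-ring v-u-x-w for some x != v
            mid = adj[u] & adj[w]
            mid[v] = False
            if mid.any():
                return True
    return False


def greedy_step(
    A: np.ndarray, B: np.ndarray, valid_configs: Optional[set] = None
) -> Optional[tuple]:
    """One distance-reducing minimal transformation from A toward B.

    Picks atoms (i, j, k, l) with a_ij > b_ij, a_jk < b_jk, a_kl > b_kl and
    applies the forced four-bond change.  Among admissible candidates,
    prefers one whose configuration is in the canonical rule set and whose
    result respects the structural constraints.  Returns
    ``(new_A, (i, j, k, l), config)`` or None when A == B.
    """
    if valid_configs is None:
        valid_configs = set(derive_configs())
    n = A.shape[0]
    if np.array_equal(A, B):
        return None
    fallback = None
    for i in range(n):
        for j in range(n):
            if i == j or A[i, j] <= B[i, j]:
                continue
            for k in range(n):
                if k in (i, j) or A[j, k] >= B[j, k] or A[j, k] >= 3:
                    continue
                for l in range(n):
                    if l in (i, j, k) or A[k, l] <= B[k, l] or A[i, l] >= 3:
                        continue
                    cfg = BondConfiguration(
                        a12=int(A[i, j]), a23=int(A[j, k]),
                        a34=int(A[k, l]), a14=int(A[i, l]),
                    )
                    if not any(rules_are_identical(cfg, c) for c in valid_configs):
                        continue
                    A2 = A.copy()
                    A2[i, j] = A2[j, i] = cfg.b12
                    A2[j, k] = A2[k, j] = cfg.b23
                    A2[k, l] = A2[l, k] = cfg.b34
                    A2[i, l] = A2[l, i] = cfg.b14
                    candidate = (A2, (i, j, k, l), cfg)
                    if _matrix_violates_ring_rule(A2):
                        fallback = fallback or candidate
                        continue
                    return candidate
    return fallback


def _candidate_steps(A: np.ndarray, B: np.ndarray, valid_configs: set):
    """All canonical-rule applications on A that strictly reduce S toward B.

    Results that respect the structural constraints are yielded before those
    that do not, so a monotone walk through valid intermediates is preferred.
    """
    n = A.shape[0]
    deferred = []
    for i in range(n):
        for j in range(n):
            if i == j or A[i, j] <= B[i, j]:
                continue
            for k in range(n):
                if k in (i, j) or A[j, k] >= B[j, k]:
                    continue
                for l in range(n):
                    if l in (i, j, k) or A[k, l] <= B[k, l] or A[i, l] >= 3:
                        continue
                    cfg = BondConfiguration(
                        a12=int(A[i, j]), a23=int(A[j, k]),
                        a34=int(A[k, l]), a14=int(A[i, l]),
                    )
                    if not any(rules_are_identical(cfg, c) for c in valid_configs):
                        continue
                    A2 = A.copy()
                    A2[i, j] = A2[j, i] = cfg.b12
                    A2[j, k] = A2[k, j] = cfg.b23
                    A2[k, l] = A2[l, k] = cfg.b34
                    A2[i, l] = A2[l, i] = cfg.b14
                    candidate = (A2, (i, j, k, l), cfg)
                    if _matrix_violates_ring_rule(A2):
                        deferred.append(candidate)
                    else:
                        yield candidate
    yield from deferred


def greedy_transform(
    A: np.ndarray, B: np.ndarray, max_steps: Optional[int] = None
) -> list:
    """Transform A into B by distance-reducing minimal transformations.

    Performs a depth-first search over rule applications that strictly
    decrease the labeled distance S (each by 2 or 4, the per-step bound), so
    any returned walk has at most S/2 steps.  Greedy descent suffices for
    almost every isomer pair; backtracking covers the rare configurations
    where the first distance-reducing move dead-ends.

    Returns the list of (atoms, config, S_before, S_after) steps; raises
    :class:`RuntimeError` if no monotone walk exists.
    """
    valid = set(derive_configs())
    if max_steps is None:
        max_steps = int(bond_order_distance(A, B).S) // 2
    path: list = []

    def dfs(current: np.ndarray) -> bool:
        if np.array_equal(current, B):
            return True
        if len(path) >= max_steps:
            return False
        s_before = bond_order_distance(current, B).S
        for nxt, atoms, cfg in _candidate_steps(current, B, valid):
            s_after = bond_order_distance(nxt, B).S
            path.append((atoms, cfg, s_before, s_after))
            if dfs(nxt):
                return True
            path.pop()
        return False

    if not dfs(A.copy()):
        raise RuntimeError("no monotone transformation path found")
    return path
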