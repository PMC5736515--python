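"""Deterministic toy inputs and independent oracles.

Everything here is synthetic and generated programmatically: alkane seed
panels, hand-built atom-mapped toy reactions emulating enzymatic chemistry
(a transaminase-style amine/carbonyl exchange is replaced by a single-bond
amine/alcohol exchange so the reaction center is exactly two broken and two
formed bonds), built-in scorers for the inverse-QSAR loop, and two
brute-force generators used as independent cross-checks of the rule engine:

* free trees via :func:`networkx.nonisomorphic_trees` for alkane skeletons;
* exhaustive multigraph enumeration (bond orders 0..3, valence <= 4,
  connected, small-ring double-bond rule) for small heavy-atom structures.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from rdkit import Chem

from .chem import BOND_TYPES, Molecule, parse_molecule
from .extract import MappedReaction
from .screen import maccs_tanimoto

#: bimolecular toy: amine/alcohol exchange across two substrates —
#: two bonds broken (C-O, C-N) and two formed, a 4-atom reaction center.
#: The long alkyl tail makes the diameter truncation non-trivial: rules at
#: diameters 2..10 keep successively longer stretches of the chain.
TOY_EXCHANGE_REACTION = (
    "[CH3:1][CH2:2][CH2:3][CH2:4][CH2:5][CH:6]([OH:7])[CH3:8].[NH2:9][CH3:10]"
    ">>[CH3:1][CH2:2][CH2:3][CH2:4][CH2:5][CH:6]([NH2:9])[CH3:8].[OH:7][CH3:10]"
)

#: alcohols sharing successively less of the native substrate's context;
#: a useful panel for observing promiscuity as a function of rule diameter
SUBSTRATE_PANEL = ["CCCCCC(O)C", "CCCCC(O)C", "CCCC(O)C", "CCC(O)C", "CC(O)C"]

#: unimolecular toy: ring opening of cyclopropane to propene —
#: one bond broken, one bond order raised
TOY_RING_OPENING = "[CH2:1]1[CH2:2][CH2:3]1>>[CH2:1]=[CH:2][CH3:3]"


def linear_alkane(n_carbons: int) -> Molecule:
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    return parse_molecule("C" * n_carbons)


def alkane_panel(max_carbons: int = 14) -> list:
    """Linear alkane seeds C1..Cmax."""
    return [linear_alkane(n) for n in range(1, max_carbons + 1)]


def heavy_atom_target_scorer(target: int = 8):
    """Score = negative absolute deviation of heavy-atom count from target."""

    def score(mol: Molecule) -> float:
        return -abs(mol.heavy_atom_count - target)

    return score


def maccs_similarity_scorer(reference: Molecule):
    """Score = MACCS Tanimoto similarity to a fixed reference structure."""

    def score(mol: Molecule) -> float:
        return maccs_tanimoto(mol, reference)

    return score


BUILTIN_SCORERS = {
    "heavy-atom-8": lambda: heavy_atom_target_scorer(8),
}


@dataclass
class FixtureSet:
    """The bundled deterministic test inputs."""

    seed: int
    alkanes: list
    mapped_reactions: list
    scorers: dict = field(default_factory=dict)


def generate_fixtures(seed: int = 0) -> FixtureSet:
    """Deterministic fixture bundle: alkanes C1-C14, toy mapped reactions,
    and the built-in synthetic scorers."""
    reactions = [
        MappedReaction(TOY_EXCHANGE_REACTION, identifiers={"id": "toy-exchange"},
                       ec_annotations=["2.6.1.-"]),
        MappedReaction(TOY_RING_OPENING, identifiers={"id": "toy-ring-opening"},
                       ec_annotations=["5.4.99.-"]),
    ]
    return FixtureSet(
        seed=seed,
        alkanes=alkane_panel(14),
        mapped_reactions=reactions,
        scorers={name: make() for name, make in BUILTIN_SCORERS.items()},
    )


# ---------------------------------------------------------------------------
# Independent brute-force oracles
# ---------------------------------------------------------------------------


def free_tree_alkanes(n_carbons: int) -> set:
    """Connectivity keys of all alkane skeletons with ``n_carbons`` atoms.

    Generated by exhaustive non-isomorphic free-tree enumeration (degree
    capped at 4), entirely independently of the rule engine.
    """
    if n_carbons == 1:
        return {parse_molecule("C").canonical_key}
    keys = set()
    for tree in nx.nonisomorphic_trees(n_carbons):
        if max(dict(tree.degree).values()) > 4:
            continue
        rw = Chem.RWMol()
        for _ in range(n_carbons):
            rw.AddAtom(Chem.Atom(6))
        for u, v in tree.edges:
            rw.AddBond(u, v, Chem.BondType.SINGLE)
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        keys.add(Molecule(mol).canonical_key)
    return keys


def _valence_ok(A: np.ndarray, max_valence: int = 4) -> bool:
    return bool((A.sum(axis=0) <= max_valence).all())


def _connected(A: np.ndarray) -> bool:
    n = A.shape[0]
    seen = {0}
    frontier = [0]
    adj = A > 0
    while frontier:
        v = frontier.pop()
        for u in np.flatnonzero(adj[v]):
            if u not in seen:
                seen.add(int(u))
                frontier.append(int(u))
    return len(seen) == n


def matrix_to_molecule(A: np.ndarray) -> Molecule:
    """All-carbon molecule from a heavy-atom bond-order matrix."""
    n = A.shape[0]
    rw = Chem.RWMol()
    for _ in range(n):
        rw.AddAtom(Chem.Atom(6))
    for i in range(n):
        for j in range(i + 1, n):
            if A[i, j]:
                rw.AddBond(i, j, BOND_TYPES[int(A[i, j])])
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return Molecule(mol)


def enumerate_carbon_multigraphs(
    n_atoms: int, max_order: int = 3, max_valence: int = 4
) -> list:
    """Exhaustive connected carbon structures on ``n_atoms`` heavy atoms.

    Brute-force enumeration over all bond-order assignments of the complete
    graph, filtered by valence, connectivity and the small-ring double-bond
    rule, deduplicated at the connectivity level.  Returns one
    (adjacency_matrix, Molecule) pair per isomorphism class.

    Intended as an oracle at small ``n_atoms`` (the search space grows as
    ``(max_order + 1) ** (n(n-1)/2)``).
    """
    from .derive import _matrix_violates_ring_rule

    pairs = list(itertools.combinations(range(n_atoms), 2))
    out = []
    seen_keys = set()

    def rec(idx: int, A: np.ndarray):
        if idx == len(pairs):
            if not _connected(A) or _matrix_violates_ring_rule(A):
                return
            mol = matrix_to_molecule(A)
            if mol.canonical_key not in seen_keys:
                seen_keys.add(mol.canonical_key)
                out.append((A.copy(), mol))
            return
        i, j = pairs[idx]
        for order in range(max_order + 1):
            A[i, j] = A[j, i] = order
            if A[i].sum() <= max_valence and A[j].sum() <= max_valence:
                rec(idx + 1, A)
        A[i, j] = A[j, i] = 0

    if n_atoms == 1:
        return [(np.zeros((1, 1), dtype=int), parse_molecule("C"))]
    rec(0, np.zeros((n_atoms, n_atoms), dtype=int))
    return out


def explicit_hydrogen_matrix(A: np.ndarray, max_valence: int = 4) -> np.ndarray:
    """Extend a heavy-atom matrix with the hydrogens saturating each valence.

    Hydrogens are appended after the heavy atoms, those of atom i before
    those of atom i+1, giving every saturated structure of the same heavy
    formula an element-aligned shared indexing.
    """
    n = A.shape[0]
    h_counts = [int(max_valence - A[i].sum()) for i in range(n)]
    total = n + sum(h_counts)
    M = np.zeros((total, total), dtype=int)
    M[:n, :n] = A
    h = n
    for i, cnt in enumerate(h_counts):
        for _ in range(cnt):
            M[i, h] = M[h, i] = 1
            h += 1
    return M
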