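"""Variable-diameter enzymatic reaction rules from atom-mapped reactions.

An atom-mapped reaction SMILES fixes the correspondence between substrate
and product atoms.  The *reaction center* is the set of bonds whose order
differs between the two sides.  A multi-substrate reaction is decomposed
into one component per substrate — each component models enzyme promiscuity
on that substrate, carrying the remaining substrates along as fixed
co-substrates — and each component is truncated to a series of *diameters*:
a rule of diameter d keeps only the atoms within d/2 bonds of a
reaction-center atom.  Small diameters yield permissive (promiscuous)
rules, large diameters conservative ones; at infinite diameter the rule is
the full component.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from rdkit import Chem

from .chem import Molecule, ReactionRule

logger = logging.getLogger(__name__)

VALID_DIAMETERS = (2, 4, 6, 8, 10, 12, 14, 16)


class ExtractionError(ValueError):
    """Raised for degenerate or incompletely mapped reactions."""


def _parse_side(text: str) -> list:
    frags = []
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise ExtractionError(f"could not parse reaction side {text!r}")
    for frag in Chem.GetMolFrags(mol, asMols=True):
        frags.append(frag)
    return frags


@dataclass
class MappedReaction:
    """An atom-mapped reaction SMILES split into substrate/product mols."""

    reaction_text: str
    identifiers: dict = field(default_factory=dict)
    ec_annotations: list = field(default_factory=list)

    def __post_init__(self):
        if ">>" not in self.reaction_text:
            raise ExtractionError(f"not a reaction SMILES: {self.reaction_text!r}")
        left, right = self.reaction_text.split(">>")
        self.substrates = _parse_side(left)
        self.products = _parse_side(right)
        sub_maps = [m for mol in self.substrates for m in _map_numbers(mol) if m]
        if len(sub_maps) != len(set(sub_maps)):
            raise ExtractionError("duplicate atom-map numbers on the substrate side")
        for mol in self.substrates:
            maps = _map_numbers(mol)
            # a fragment with no map numbers at all is an unmapped spectator;
            # partially mapped substrates indicate a broken mapping
            if any(maps) and not all(maps):
                raise ExtractionError(
                    "substrate heavy atoms without atom-map numbers: mapping incomplete"
                )
        prod_maps = {m for mol in self.products for m in _map_numbers(mol) if m}
        if not prod_maps.issubset(set(sub_maps)):
            raise ExtractionError(
                "product atom-map numbers missing from the substrate side"
            )

    @property
    def substrate_count(self) -> int:
        return len(self.substrates)


def _map_numbers(mol: Chem.Mol) -> list:
    return [a.GetAtomMapNum() for a in mol.GetAtoms()]


def _bond_orders_by_map(mols: Iterable[Chem.Mol]) -> dict:
    orders = {}
    for mol in mols:
        for b in mol.GetBonds():
            mi = b.GetBeginAtom().GetAtomMapNum()
            mj = b.GetEndAtom().GetAtomMapNum()
            if mi and mj:
                orders[frozenset((mi, mj))] = int(b.GetBondTypeAsDouble())
    return orders


@dataclass(frozen=True)
class ReactionCenter:
    """Bonds whose order changes, with delta = product minus substrate order."""

    changed_bonds: frozenset  # of (map_i, map_j, delta), map_i < map_j
    center_atoms: frozenset  # map numbers incident to a changed bond


def find_reaction_center(rxn: MappedReaction) -> ReactionCenter:
    """Locate all broken, formed and order-shifted bonds of a mapped reaction."""
    before = _bond_orders_by_map(rxn.substrates)
    after = _bond_orders_by_map(rxn.products)
    changed = set()
    for pair in set(before) | set(after):
        delta = after.get(pair, 0) - before.get(pair, 0)
        if delta != 0:
            i, j = sorted(pair)
            changed.add((i, j, delta))
    if not changed:
        raise ExtractionError("degenerate reaction: no bond order changes")
    atoms = frozenset(itertools.chain.from_iterable((i, j) for i, j, _ in changed))
    return ReactionCenter(frozenset(changed), atoms)


@dataclass
class RuleComponent:
    """The per-substrate slice of a reaction used to model promiscuity.

    ``products`` are the product fragments sharing at least one mapped atom
    with the focal substrate; the other substrates ride along as fixed
    co-substrates so only one substrate varies when the rule is applied.
    """

    substrate: Chem.Mol
    co_substrates: list
    products: list
    reaction: MappedReaction


def decompose_components(rxn: MappedReaction) -> list:
    """One :class:`RuleComponent` per substrate of the reaction."""
    components = []
    for idx, sub in enumerate(rxn.substrates):
        sub_maps = {m for m in _map_numbers(sub) if m}
        if not sub_maps:
            # unmapped spectator (e.g. solvent water): not a rule component
            continue
        prods = [
            p
            for p in rxn.products
            if sub_maps & {m for m in _map_numbers(p) if m}
        ]
        if not prods:
            logger.warning(
                "substrate %d of %r contributes no atom to any product",
                idx,
                rxn.reaction_text,
            )
        components.append(
            RuleComponent(
                substrate=sub,
                co_substrates=[s for i, s in enumerate(rxn.substrates) if i != idx],
                products=prods,
                reaction=rxn,
            )
        )
    return components


def _kept_atoms(mol: Chem.Mol, center_maps: frozenset, radius: float) -> list:
    """Atom indices within ``radius`` bonds of a reaction-center atom.

    Distances are counted over heavy atoms only; atoms created by the
    reaction (unmapped on the product side) are always kept.
    """
    seeds = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomMapNum() in center_maps]
    created = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomMapNum() == 0]
    if math.isinf(radius):
        return list(range(mol.GetNumAtoms()))
    keep = set(created)
    frontier = set(seeds)
    keep |= frontier
    for _ in range(int(radius)):
        nxt = set()
        for idx in frontier:
            for nbr in mol.GetAtomWithIdx(idx).GetNeighbors():
                if nbr.GetIdx() not in keep:
                    nxt.add(nbr.GetIdx())
        keep |= nxt
        frontier = nxt
    return sorted(keep)


def _fragment_smarts(mol: Chem.Mol, atoms: Sequence[int]) -> Optional[str]:
    if not atoms:
        return None
    return Chem.MolFragmentToSmiles(
        mol, atomsToUse=list(atoms), canonical=True, allHsExplicit=False
    )


def extract_rule(
    component: RuleComponent,
    diameter: float,
    center: Optional[ReactionCenter] = None,
) -> ReactionRule:
    """Truncate ``component`` to ``diameter`` and emit a reaction SMARTS rule.

    Keeps exactly the atoms within ``diameter/2`` bonds of any
    reaction-center atom (all atoms at infinite diameter), preserving atom
    maps, charges and aromatic flags.  A molecule of the component that
    retains no atoms at this diameter is dropped from the rule.
    """
    if not math.isinf(diameter):
        if diameter not in VALID_DIAMETERS:
            raise ExtractionError(
                f"diameter must be an even integer in {VALID_DIAMETERS} or inf"
            )
    center = center or find_reaction_center(component.reaction)
    radius = diameter / 2
    reactant_mols = [component.substrate] + list(component.co_substrates)
    lhs = [
        _fragment_smarts(m, _kept_atoms(m, center.center_atoms, radius))
        for m in reactant_mols
    ]
    rhs = [
        _fragment_smarts(m, _kept_atoms(m, center.center_atoms, radius))
        for m in component.products
    ]
    lhs = [s for s in lhs if s]
    rhs = [s for s in rhs if s]
    if not lhs or not rhs:
        raise ExtractionError("rule truncation removed an entire reaction side")
    diameter_tag = "inf" if math.isinf(diameter) else str(int(diameter))
    sub_id = component.reaction.identifiers.get("id", "rxn")
    smarts = ".".join(lhs) + ">>" + ".".join(rhs)
    return ReactionRule(
        rule_id=f"{sub_id}-d{diameter_tag}",
        smarts=smarts,
        n_reactant_components=len(lhs),
        diameter=diameter,
        ec_annotations=list(component.reaction.ec_annotations),
    )


def extract_rules(
    reactions: Iterable[MappedReaction],
    diameters: Sequence[float] = VALID_DIAMETERS,
) -> list:
    """All (component, diameter) rules of a reaction collection."""
    rules = []
    for rxn in reactions:
        center = find_reaction_center(rxn)
        for comp_idx, comp in enumerate(decompose_components(rxn)):
            if not comp.products:
                continue
            for d in diameters:
                rule = extract_rule(comp, d, center)
                rule.rule_id = (
                    f"{rxn.identifiers.get('id', 'rxn')}-c{comp_idx}-d"
                    f"{'inf' if math.isinf(d) else int(d)}"
                )
                rules.append(rule)
    return rules


def accepts_substrate(rule: ReactionRule, substrate: Molecule, co_substrates=()) -> bool:
    """Whether the rule fires on ``substrate`` (with its native co-substrates)."""
    from .chem import apply_rule

    reactants = [substrate] + [Molecule(m) for m in co_substrates]
    if len(reactants) != rule.n_reactant_components:
        return False
    try:
        return bool(apply_rule(rule, reactants))
    except Exception:
        return False
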