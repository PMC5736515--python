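"""Molecule and reaction-rule primitives shared by every other module.

Molecules are thin wrappers around RDKit mols carrying a *connectivity-level*
canonical key: two input strings that encode the same atom/bond skeleton map
to the same key regardless of stereo descriptors or explicit-hydrogen
notation.  Reaction rules are reaction SMARTS; they are applied by pattern
embedding, and every product is sanitized, deduplicated by canonical key and
passed through the structural filters (connectivity, maximal valence,
small-ring double-bond exclusion) that define the admissible chemical space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem
from rdkit.Chem.rdMolDescriptors import CalcMolFormula

RDLogger.DisableLog("rdApp.*")

BOND_TYPES = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}


class MoleculeError(ValueError):
    """Raised when a structure string cannot be parsed or sanitized."""


class RuleError(ValueError):
    """Raised when a reaction SMARTS cannot be parsed or applied."""


def _strip_and_canonicalize(mol: Chem.Mol) -> str:
    """Stereo-free, hydrogen-normalized canonical SMILES of ``mol``."""
    m = Chem.RemoveHs(Chem.Mol(mol))
    Chem.RemoveStereochemistry(m)
    for atom in m.GetAtoms():
        atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(m)


class Molecule:
    """A sanitized molecular graph with a connectivity-level identity.

    Parameters
    ----------
    mol:
        A sanitized RDKit molecule.
    hydrogen_mode:
        ``"implicit"`` keeps hydrogens implicit; ``"explicit"`` saturates
        every valence with explicit hydrogen atoms so that rule patterns can
        match hydrogens as ordinary atoms.
    """

    __slots__ = ("rdmol", "hydrogen_mode", "_key")

    def __init__(self, mol: Chem.Mol, hydrogen_mode: str = "implicit"):
        if hydrogen_mode not in ("implicit", "explicit"):
            raise ValueError(f"unknown hydrogen_mode {hydrogen_mode!r}")
        self.hydrogen_mode = hydrogen_mode
        self.rdmol = Chem.AddHs(mol) if hydrogen_mode == "explicit" else mol
        self._key: Optional[str] = None

    @property
    def canonical_key(self) -> str:
        if self._key is None:
            self._key = _strip_and_canonicalize(self.rdmol)
        return self._key

    @property
    def structure_text(self) -> str:
        return Chem.MolToSmiles(self.rdmol)

    @property
    def heavy_atom_count(self) -> int:
        return sum(1 for a in self.rdmol.GetAtoms() if a.GetAtomicNum() != 1)

    @property
    def formula(self) -> str:
        return CalcMolFormula(self.rdmol)

    @property
    def num_components(self) -> int:
        return len(Chem.GetMolFrags(self.rdmol))

    def to_explicit(self) -> "Molecule":
        if self.hydrogen_mode == "explicit":
            return self
        return Molecule(self.rdmol, hydrogen_mode="explicit")

    def to_implicit(self) -> "Molecule":
        if self.hydrogen_mode == "implicit":
            return self
        return Molecule(Chem.RemoveHs(self.rdmol), hydrogen_mode="implicit")

    def __eq__(self, other) -> bool:
        return isinstance(other, Molecule) and self.canonical_key == other.canonical_key

    def __hash__(self) -> int:
        return hash(self.canonical_key)

    def __repr__(self) -> str:
        return f"Molecule({self.canonical_key!r})"


def parse_molecule(text: str, hydrogen_mode: str = "implicit") -> Molecule:
    """Parse a SMILES or InChI string into a sanitized :class:`Molecule`.

    Raises :class:`MoleculeError` naming the offending text on failure.
    """
    if not text or not text.strip():
        raise MoleculeError("empty structure string")
    text = text.strip()
    if text.startswith("InChI="):
        mol = Chem.MolFromInchi(text)
    else:
        mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise MoleculeError(f"could not parse structure {text!r}")
    return Molecule(mol, hydrogen_mode=hydrogen_mode)


@dataclass
class FilterReport:
    """Bookkeeping of how many candidate structures each filter removed."""

    input_count: int = 0
    rejected_disconnected: int = 0
    rejected_valence: int = 0
    rejected_ring_constraint: int = 0
    rejected_sanitization: int = 0
    retained: int = 0

    def merge(self, other: "FilterReport") -> "FilterReport":
        return FilterReport(
            self.input_count + other.input_count,
            self.rejected_disconnected + other.rejected_disconnected,
            self.rejected_valence + other.rejected_valence,
            self.rejected_ring_constraint + other.rejected_ring_constraint,
            self.rejected_sanitization + other.rejected_sanitization,
            self.retained + other.retained,
        )


@dataclass
class ReactionRule:
    """A reaction SMARTS with arity, diameter and annotations.

    ``config`` is set for the four-atom bond-rearrangement rules emitted by
    :mod:`rxnspace.derive`; when present the enumeration engine can use a
    direct bond-editing applier that is exactly equivalent to (and much
    faster than) the generic SMARTS pattern-embedding route.
    """

    rule_id: str
    smarts: str
    n_reactant_components: Optional[int] = None
    diameter: float = float("inf")
    direction: str = "forward"
    ec_annotations: list = field(default_factory=list)
    config: Optional[object] = None  # BondConfiguration for derived rules

    _rxn: Optional[AllChem.ChemicalReaction] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self):
        try:
            rxn = AllChem.ReactionFromSmarts(self.smarts)
        except Exception as exc:
            raise RuleError(
                f"invalid reaction SMARTS for {self.rule_id!r}: {self.smarts!r} ({exc})"
            ) from exc
        if rxn is None:
            raise RuleError(f"invalid reaction SMARTS for {self.rule_id!r}: {self.smarts!r}")
        rxn.Initialize()
        object.__setattr__(self, "_rxn", rxn)
        if self.n_reactant_components is None:
            self.n_reactant_components = rxn.GetNumReactantTemplates()
        elif self.n_reactant_components != rxn.GetNumReactantTemplates():
            raise RuleError(
                f"rule {self.rule_id!r}: declared {self.n_reactant_components} reactant "
                f"components but SMARTS has {rxn.GetNumReactantTemplates()}"
            )

    @property
    def rxn(self) -> AllChem.ChemicalReaction:
        return self._rxn


def _sanitize_product(mol: Chem.Mol) -> Optional[Chem.Mol]:
    """Sanitize a raw rule product; return None if chemistry is unsound.

    Products carrying radical electrons are rejected: with hydrogen-explicit
    graphs a radical can only arise from a spurious embedding in which a
    "created" bond already existed, which silently deletes a valence.
    """
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    if any(a.GetNumRadicalElectrons() for a in mol.GetAtoms()):
        return None
    return mol


def _atom_counts(mol: Chem.Mol):
    """Element -> count over all atoms, implicit hydrogens included."""
    counts: dict = {}
    for a in mol.GetAtoms():
        counts[a.GetAtomicNum()] = counts.get(a.GetAtomicNum(), 0) + 1
        counts[1] = counts.get(1, 0) + a.GetTotalNumHs(includeNeighbors=False)
    return counts


def apply_rule(
    rule: ReactionRule,
    reactants: Sequence[Molecule],
    report: Optional[FilterReport] = None,
) -> set:
    """Apply ``rule`` to an ordered reactant list.

    Every embedding of the reactant pattern yields one product tuple; bonds
    between mapped atoms that the pattern does not mention are preserved
    unchanged.  Products are sanitized and merged at the connectivity level;
    failures are silently dropped (and counted when ``report`` is given).

    For the derived bond-rearrangement rules (``rule.config`` set) the
    reactants are kekulized first and product tuples that do not conserve
    the molecular formula are rejected: a bond-order rearrangement can never
    change the atom inventory, so a formula change flags an embedding in
    which a bond to be created already existed and the pattern engine
    silently refilled the lost valence with hydrogens.

    Returns a set of product tuples (tuples of :class:`Molecule`).
    """
    if len(reactants) != rule.n_reactant_components:
        raise RuleError(
            f"rule {rule.rule_id!r} expects {rule.n_reactant_components} reactants, "
            f"got {len(reactants)}"
        )
    rdmols = [m.rdmol for m in reactants]
    expected_counts = None
    if rule.config is not None:
        kekulized = []
        for m in rdmols:
            k = Chem.Mol(m)
            Chem.Kekulize(k, clearAromaticFlags=True)
            kekulized.append(k)
        rdmols = kekulized
        expected_counts = {}
        for m in rdmols:
            for el, n in _atom_counts(m).items():
                expected_counts[el] = expected_counts.get(el, 0) + n
    try:
        raw = rule.rxn.RunReactants(tuple(rdmols), maxProducts=0)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuleError(f"rule {rule.rule_id!r} failed to run: {exc}") from exc
    out = {}
    n_bad = 0
    for prod_tuple in raw:
        sane = []
        for p in prod_tuple:
            sp = _sanitize_product(p)
            if sp is None:
                sane = None
                break
            sane.append(Molecule(sp))
        if sane is None:
            n_bad += 1
            continue
        if expected_counts is not None:
            got: dict = {}
            for m in sane:
                for el, n in _atom_counts(m.rdmol).items():
                    got[el] = got.get(el, 0) + n
            if got != expected_counts:
                n_bad += 1
                continue
        key = tuple(sorted(m.canonical_key for m in sane))
        out.setdefault(key, tuple(sane))
    if report is not None:
        report.input_count += len(raw)
        report.rejected_sanitization += n_bad
        report.retained += len(out)
    return set(out.values())


def filter_connected(mols: Iterable[Molecule]) -> tuple[set, FilterReport]:
    """Retain only single-component structures."""
    report = FilterReport()
    kept = set()
    for m in mols:
        report.input_count += 1
        if m.num_components > 1:
            report.rejected_disconnected += 1
        else:
            kept.add(m)
            report.retained += 1
    return kept, report


def _violates_small_ring_rule(mol: Chem.Mol) -> bool:
    """True if some atom in a 3- or 4-membered ring carries two double bonds."""
    for atom in mol.GetAtoms():
        n_double = sum(
            1 for b in atom.GetBonds() if b.GetBondType() == Chem.BondType.DOUBLE
        )
        if n_double >= 2 and (atom.IsInRingSize(3) or atom.IsInRingSize(4)):
            return True
    return False


def filter_valence_and_rings(
    mols: Iterable[Molecule], max_valence: int = 4
) -> tuple[set, FilterReport]:
    """Reject hypervalent atoms and double-bond-crowded small rings.

    A structure is dropped if any atom has total bond order above
    ``max_valence``, or if an atom carrying two double bonds sits in a 3- or
    4-membered ring (geometrically impossible for tetravalent chemistry).
    """
    report = FilterReport()
    kept = set()
    for m in mols:
        report.input_count += 1
        mol = m.rdmol
        if any(a.GetTotalValence() > max_valence for a in mol.GetAtoms()):
            report.rejected_valence += 1
            continue
        if _violates_small_ring_rule(mol):
            report.rejected_ring_constraint += 1
            continue
        kept.add(m)
        report.retained += 1
    return kept, report


def merge_by_key(mols: Iterable[Molecule]) -> dict:
    """Deduplicate molecules at the connectivity level; key -> molecule."""
    out = {}
    for m in mols:
        out.setdefault(m.canonical_key, m)
    return out
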