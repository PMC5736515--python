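"""Breadth-first rule-application engine for chemical-space generation.

The core loop fires every rule on every structure of a *source* set,
sanitizes and filters the products, removes everything already recorded in
the *sink* (the set of all structures seen so far), and promotes the
remaining novelties to the next iteration's source.  Two enumeration modes
are built on top of it:

* canonical augmentation — grow skeletons one atom per iteration starting
  from a single unbonded carbon;
* isomer transformation — start from one hydrogen-saturated molecule and
  apply valence-conserving bond rearrangements until no new constitutional
  isomer appears.

A FIFO-queue variant processes the source in small chunks, trading peak
memory for bookkeeping, and provably generates the same final set.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from rdkit import Chem

from .chem import (
    FilterReport,
    Molecule,
    ReactionRule,
    _violates_small_ring_rule,
    apply_rule,
    filter_valence_and_rings,
)
from .derive import apply_config


class ConfigurationError(ValueError):
    """Raised for unusable engine parameters (empty rules, bad iteration caps)."""


@dataclass
class ProvenanceRecord:
    product_key: str
    parent_keys: tuple
    rule_id: str
    iteration: int


@dataclass
class EnumerationState:
    """Mutable state of the breadth-first engine."""

    iteration: int = 0
    source: list = field(default_factory=list)
    sink: dict = field(default_factory=dict)  # canonical_key -> Molecule
    records: list = field(default_factory=list)
    report: FilterReport = field(default_factory=FilterReport)

    @classmethod
    def from_seeds(cls, seeds: Iterable[Molecule]) -> "EnumerationState":
        state = cls()
        for m in seeds:
            if m.canonical_key not in state.sink:
                state.sink[m.canonical_key] = m
                state.source.append(m)
                state.records.append(
                    ProvenanceRecord(m.canonical_key, (), "seed", 0)
                )
        return state

    @property
    def structures(self) -> set:
        return set(self.sink.values())


def _fire_rule_on(rule: ReactionRule, mol: Molecule) -> list:
    """Raw (unfiltered) RDKit product mols of one rule on one structure."""
    if rule.config is not None:
        return apply_config(rule.config, mol.rdmol)
    products = []
    for tup in apply_rule(rule, [mol]):
        products.extend(m.rdmol for m in tup)
    return products


def _clean_products(
    raw: Iterable[Chem.Mol],
    hydrogen_mode: str,
    report: FilterReport,
    require_triangle_free: bool = False,
    provenance: Optional[list] = None,
) -> list:
    """Sanitize, connectivity/valence-filter and wrap raw product mols.

    Returns wrapped molecules, or (molecule, parent_keys, rule_id) triples
    when ``provenance`` (a parallel list of (parent_keys, rule_id)) is given.
    """
    out = []
    for idx, p in enumerate(raw):
        report.input_count += 1
        if len(Chem.GetMolFrags(p)) > 1:
            report.rejected_disconnected += 1
            continue
        try:
            Chem.SanitizeMol(p)
        except Exception:
            report.rejected_sanitization += 1
            continue
        if any(a.GetNumRadicalElectrons() for a in p.GetAtoms()):
            report.rejected_sanitization += 1
            continue
        if any(a.GetTotalValence() > 4 for a in p.GetAtoms()):
            report.rejected_valence += 1
            continue
        if _violates_small_ring_rule(p):
            report.rejected_ring_constraint += 1
            continue
        if require_triangle_free and any(a.IsInRingSize(3) for a in p.GetAtoms()):
            report.rejected_ring_constraint += 1
            continue
        report.retained += 1
        wrapped = Molecule(p, hydrogen_mode=hydrogen_mode)
        if provenance is None:
            out.append(wrapped)
        else:
            parents, rule_id = provenance[idx]
            out.append((wrapped, parents, rule_id))
    return out


def expand_once(
    state: EnumerationState,
    rules: Sequence[ReactionRule],
    require_triangle_free: bool = False,
) -> EnumerationState:
    """Run one breadth-first iteration in place and return the state.

    Fires every rule on every source structure (ordered source pairs for
    two-component rules), filters products, and promotes structures whose
    connectivity key is not yet in the sink.
    """
    if not rules:
        raise ConfigurationError("empty rule list")
    hydrogen_mode = state.source[0].hydrogen_mode if state.source else "implicit"
    raw = []  # (raw product mol, parent keys, rule id)
    for rule in rules:
        if rule.n_reactant_components == 2:
            for a in state.source:
                for b in state.source:
                    for tup in apply_rule(rule, [a, b], state.report):
                        raw.extend(
                            (m.rdmol, (a.canonical_key, b.canonical_key), rule.rule_id)
                            for m in tup
                        )
        else:
            for m in state.source:
                raw.extend(
                    (p, (m.canonical_key,), rule.rule_id)
                    for p in _fire_rule_on(rule, m)
                )
    products = _clean_products(
        (p for p, _, _ in raw), hydrogen_mode, state.report, require_triangle_free,
        provenance=[(parents, rid) for _, parents, rid in raw],
    )
    state.iteration += 1
    new_source = []
    for p, parents, rule_id in products:
        key = p.canonical_key
        if key in state.sink:
            continue
        state.sink[key] = p
        new_source.append(p)
        state.records.append(ProvenanceRecord(key, parents, rule_id, state.iteration))
    state.source = new_source
    return state


@dataclass
class EnumerationResult:
    structures: set
    last_new_iteration: int
    n_iterations: int
    per_iteration_new: list
    report: FilterReport
    records: list = field(default_factory=list)


def enumerate_isomers(
    seed: Molecule,
    rules: Sequence[ReactionRule],
    max_iter: int = 1000,
) -> EnumerationResult:
    """Enumerate all constitutional isomers reachable from ``seed``.

    The seed is hydrogen-saturated and the rules are fired breadth-first
    until an iteration produces nothing new (or ``max_iter`` is hit).

    ``n_iterations`` counts every rule-firing round executed, including the
    terminal round that yields no novelty — the convention under which the
    published alkane iteration counts are reported.  ``last_new_iteration``
    is the round at which the final novel structure appeared.
    """
    if max_iter <= 0:
        raise ConfigurationError("max_iter must be positive")
    seed_ok, _ = filter_valence_and_rings([seed])
    if not seed_ok:
        raise ConfigurationError("seed fails the structural filters")
    state = EnumerationState.from_seeds([seed.to_explicit()])
    per_iteration = []
    last_new = 0
    n_rounds = 0
    while state.source and n_rounds < max_iter:
        expand_once(state, rules)
        n_rounds += 1
        per_iteration.append(len(state.source))
        if state.source:
            last_new = state.iteration
    return EnumerationResult(
        structures={m.to_implicit() for m in state.structures},
        last_new_iteration=last_new,
        n_iterations=n_rounds,
        per_iteration_new=per_iteration,
        report=state.report,
        records=state.records,
    )


def augmentation_rules(max_attachment_bonds: int = 1) -> list:
    """Canonical-augmentation rules: attach one new carbon by 1..4 bonds.

    Rule ``A1`` grows acyclic skeletons; ``A2``-``A4`` bond the new atom to
    several existing atoms and therefore create rings.  Attachment atoms
    must be pairwise non-adjacent (enforced downstream by rejecting
    3-membered rings), so the generated skeletons are triangle-free.
    """
    grower = "[C;D0,D1,D2,D3:{i}]"
    rules = []
    for k in range(1, max_attachment_bonds + 1):
        lhs = ".".join(grower.format(i=i) for i in range(1, k + 1))
        # product: one new carbon bonded to every pattern atom
        if k == 1:
            rhs = "[*:1]C"
        else:
            branches = "".join(f"([*:{i}])" for i in range(2, k))
            rhs = f"[*:1]C{branches}[*:{k}]"
        rules.append(ReactionRule(rule_id=f"A{k}", smarts=f"({lhs})>>({rhs})"))
    return rules


def canonical_augmentation(
    max_atoms: int,
    rules: Optional[Sequence[ReactionRule]] = None,
) -> tuple[set, Counter]:
    """Grow carbon skeletons one atom per iteration from a single carbon.

    Runs ``max_atoms - 1`` iterations and returns the cumulative set of all
    structures generated (the seed included) together with a Counter of
    structures per heavy-atom count.  With the single-bond rule only, every
    structure is an acyclic skeleton.
    """
    if max_atoms < 1:
        raise ConfigurationError("max_atoms must be >= 1")
    if rules is None:
        rules = augmentation_rules(1)
    seed = Molecule(Chem.MolFromSmiles("C"))
    state = EnumerationState.from_seeds([seed])
    for _ in range(max_atoms - 1):
        if not state.source:
            break
        expand_once(state, rules, require_triangle_free=True)
    structures = state.structures
    per_size = Counter(m.heavy_atom_count for m in structures)
    return structures, per_size


def enumerate_queue(
    seed: Molecule,
    rules: Sequence[ReactionRule],
    chunk_size: int = 20,
    max_structures: Optional[int] = None,
) -> set:
    """FIFO-queue chunked variant of :func:`enumerate_isomers`.

    Structures are popped from a queue in chunks of at most ``chunk_size``,
    rules are fired on the chunk, and novel products are appended to the
    queue.  The final structure set is identical to the breadth-first one;
    only memory usage and processing order differ.
    """
    if chunk_size < 1:
        raise ConfigurationError("chunk_size must be >= 1")
    seed = seed.to_explicit()
    sink = {seed.canonical_key: seed}
    queue = deque([seed])
    report = FilterReport()
    while queue:
        chunk = [queue.popleft() for _ in range(min(chunk_size, len(queue)))]
        raw = []
        for rule in rules:
            for m in chunk:
                raw.extend(_fire_rule_on(rule, m))
        for p in _clean_products(raw, "explicit", report):
            key = p.canonical_key
            if key not in sink:
                sink[key] = p
                queue.append(p)
        if max_structures is not None and len(sink) > max_structures:
            raise ConfigurationError("structure budget exceeded")
    return {m.to_implicit() for m in sink.values()}
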