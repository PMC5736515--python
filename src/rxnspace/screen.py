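"""Stochastic chemical-space search with similarity filtering.

Two screening primitives sit on top of the rule engine:

* similarity filtering — retain generated structures whose MACCS-key
  Tanimoto similarity to a reference exceeds a threshold;
* inverse-QSAR tournament search — iteratively sample molecules from the
  population, fire the rules, score the products with a pluggable scorer
  (a deterministic molecule -> activity mapping, higher is better), merge
  with the incumbent population, and keep the top scorers of each of
  ``n_subsets`` random subsets.

The tournament is elitist: the global best of the merged set always tops
its own subset, so the best score of the trajectory never decreases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import DataStructs, MACCSkeys

from .chem import Molecule, ReactionRule, apply_rule, filter_valence_and_rings
from .derive import apply_config

logger = logging.getLogger(__name__)

#: a scorer maps a Molecule to a real-valued activity, higher is better
Scorer = Callable[[Molecule], float]


def maccs_tanimoto(a: Molecule, b: Molecule) -> float:
    """Tanimoto similarity of MACCS structural-key fingerprints."""
    fa = MACCSkeys.GenMACCSKeys(a.rdmol)
    fb = MACCSkeys.GenMACCSKeys(b.rdmol)
    return DataStructs.TanimotoSimilarity(fa, fb)


def similarity_filter(
    mols: Iterable[Molecule], reference: Molecule, threshold: float = 0.5
) -> set:
    """Retain structures with MACCS Tanimoto similarity > ``threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    ref_fp = MACCSkeys.GenMACCSKeys(reference.rdmol)
    out = set()
    for m in mols:
        if DataStructs.TanimotoSimilarity(ref_fp, MACCSkeys.GenMACCSKeys(m.rdmol)) > threshold:
            out.add(m)
    return out


@dataclass
class TournamentConfig:
    """Selection parameters: split into ``n_subsets``, keep ``top_k`` of each."""

    n_subsets: int = 10
    top_k: int = 10
    rng_seed: int = 0
    iterations: int = 100

    def __post_init__(self):
        if self.n_subsets < 1 or self.top_k < 1:
            raise ValueError("n_subsets and top_k must be >= 1")


@dataclass
class Trajectory:
    """Per-iteration (best score, mean score, population size)."""

    best_score: list = field(default_factory=list)
    mean_score: list = field(default_factory=list)
    population_size: list = field(default_factory=list)

    def record(self, scores: Sequence[float]):
        self.best_score.append(float(max(scores)))
        self.mean_score.append(float(np.mean(scores)))
        self.population_size.append(len(scores))

    def __len__(self) -> int:
        return len(self.best_score)


def tournament_select(
    scored: dict,
    config: TournamentConfig,
    rng: np.random.Generator,
) -> set:
    """Random-subset tournament over ``scored`` (Molecule -> score).

    The merged candidates are shuffled into ``n_subsets`` subsets whose
    sizes differ by at most one; the ``top_k`` best of each subset survive.
    Score ties break on the canonical key so selection is deterministic
    under a fixed generator.  The global best always survives.
    """
    if not scored:
        raise ValueError("empty candidate set")
    mols = sorted(scored, key=lambda m: m.canonical_key)
    perm = rng.permutation(len(mols))
    subsets = [[] for _ in range(config.n_subsets)]
    for pos, idx in enumerate(perm):
        subsets[pos % config.n_subsets].append(mols[idx])
    kept = set()
    for subset in subsets:
        subset.sort(key=lambda m: (-scored[m], m.canonical_key))
        kept.update(subset[: config.top_k])
    return kept


def _fire_rules_on_sample(
    rules: Sequence[ReactionRule],
    sample: Sequence[Molecule],
) -> set:
    """Products of every rule on the sampled molecule(s).

    Bond-rearrangement rules span the combined graph of the sample so that
    fragments can be exchanged between two molecules; the (possibly
    disconnected) product is split back into its component molecules.
    Generic rules consume as many molecules as they declare reactant
    components.
    """
    products = set()
    for rule in rules:
        if rule.config is not None:
            combined = sample[0].rdmol
            for extra in sample[1:]:
                combined = Chem.CombineMols(combined, extra.rdmol)
            combined = Chem.AddHs(combined)
            for raw in apply_config(rule.config, combined):
                for frag in Chem.GetMolFrags(raw, asMols=True, sanitizeFrags=False):
                    try:
                        Chem.SanitizeMol(frag)
                    except Exception:
                        continue
                    if any(a.GetNumRadicalElectrons() for a in frag.GetAtoms()):
                        continue
                    products.add(Molecule(Chem.RemoveHs(frag)))
        else:
            reactants = list(sample[: rule.n_reactant_components])
            if len(reactants) < rule.n_reactant_components:
                continue
            try:
                for tup in apply_rule(rule, reactants):
                    products.update(m for m in tup)
            except Exception:
                continue
    kept, _ = filter_valence_and_rings(products)
    return kept


def inverse_qsar_search(
    sources: Iterable[Molecule],
    rules: Sequence[ReactionRule],
    scorer: Scorer,
    config: TournamentConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[Trajectory, set]:
    """Stochastic structure optimization against a scorer.

    Each iteration samples one molecule (two when any bond-rearrangement
    rule is present, so fragments can cross between structures), fires the
    rules, scores the products, merges them with the current population and
    tournament-selects the next population.  Products the scorer rejects
    (raises on) are dropped with a warning.

    Returns the trajectory and the final population.
    """
    population = {m.to_implicit() for m in sources}
    if not population:
        raise ValueError("empty source set")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    n_sample = 2 if any(r.config is not None for r in rules) else max(
        (r.n_reactant_components or 1) for r in rules
    ) if rules else 1
    trajectory = Trajectory()
    scores = {}
    for it in range(config.iterations):
        for m in population:
            if m not in scores:
                scores[m] = _safe_score(scorer, m)
        pool = sorted((m for m in population if scores[m] is not None),
                      key=lambda m: m.canonical_key)
        if not pool:
            raise ValueError("scorer rejected the entire population")
        idx = rng.choice(len(pool), size=min(n_sample, len(pool)), replace=False)
        sample = [pool[i] for i in idx]
        products = _fire_rules_on_sample(rules, sample)
        merged = {}
        for m in set(pool) | products:
            if m not in scores:
                scores[m] = _safe_score(scorer, m)
            if scores[m] is not None:
                merged[m] = scores[m]
        population = tournament_select(merged, config, rng)
        pop_scores = [scores[m] for m in population]
        trajectory.record(pop_scores)
    return trajectory, population


def _safe_score(scorer: Scorer, mol: Molecule) -> Optional[float]:
    try:
        return float(scorer(mol))
    except Exception as exc:
        logger.warning("scorer failed on %s: %s", mol.canonical_key, exc)
        return None
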