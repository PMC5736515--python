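# Methods

## The core loop

All generation modes share one breadth-first procedure
(`rxnspace.enumerate`). An iteration fires every rule on every structure of
the current *source* set, sanitizes the raw products, applies the
structural filters, merges duplicates at the connectivity level, and
promotes products whose canonical key is absent from the *sink* (the set
of everything seen so far) to be the next source. The loop ends when an
iteration yields nothing new or an iteration cap is reached.

Structural filters, in order:

1. **connectivity** — products with more than one component are dropped
   (when enumerating alkanes, roughly half to two thirds of raw products
   are disconnected, e.g. a ring plus an expelled H2);
2. **sanitization** — RDKit valence/aromaticity sanitization; products
   carrying radical electrons are also dropped, since on a
   hydrogen-explicit graph a radical can only arise from a spurious
   embedding (see *Rule application*, below);
3. **valence** — no atom may exceed total bond order 4;
4. **small-ring geometry** — no atom carrying two double bonds may sit in
   a 3- or 4-membered ring (sp-carbon geometry cannot close such rings).

Iteration counting: `n_iterations` counts every rule-firing round
executed, *including* the terminal round that produces nothing new;
`last_new_iteration` is the round at which the final novel structure
appeared. The classical published iteration numbers for the alkane series
follow the first convention (pentane: novelties in rounds 1 and 2, closure
confirmed in round 3 → "3 iterations"), which is why both are reported.

## Canonical identity

Molecules are compared by a connectivity-level canonical key: the
canonical SMILES of the structure after removing explicit hydrogens and
stereo descriptors. Two inputs encoding the same atom/bond skeleton —
SMILES or InChI, with or without stereo annotations — share a key. The key
deliberately ignores stereochemistry: only constitutional isomers are
enumerated.

## The 19 minimal transformation rules

`rxnspace.derive` re-derives the rule set rather than shipping strings.
Starting from the four-atom bond rearrangement (delete 1–2 and 3–4 by one
order, create 2–3 and 1–4 by one order; the diagonals 1–3 and 2–4 are
untouched and unconstrained), the derivation enumerates the 81 solvable
order assignments, keeps one representative per symmetry class
(a14 ≥ a23, a12 ≥ a34 → 36), removes the 9 assignments that would need a
valence of five (a12 = 3, a14 = 2 → 27), and removes the 8 whose reactant
or product side forces two double bonds on one atom of a small ring → 19.

Rules are numbered R1..R19 by lexicographic order of
(a12, a23, a34, a14). Rule *identity* is tested by searching the 24 label
permutations for one that maps the full edge data (initial order, final
order, diagonals marked "any") of one rule onto the other; the 19 are
pairwise distinct and closed under reversal. The reversal map is an
involution with exactly three fixed points — R1, R8 and R14 under this
numbering — which are precisely the rules that conserve the multiset of
bond orders (they relocate a single, double or triple bond without
interconverting bond types, hence never turn a multiple bond into a ring).
`bond_moving_rules()` exposes that subset for similarity-preserving
screening, and `derive_rules(include_triple_bonds=False)` the 9-rule
subset avoiding order-3 bonds. Note the numbering itself is a convention:
only the identity/reversal *structure* is meaningful, and figure-based
numberings of the same set pair differently by label.

## Rule application

Two equivalent routes apply a transformation rule to a hydrogen-explicit
molecule; tests assert their agreement over all 19 rules on a varied
panel.

* **Generic (reaction SMARTS)** — every embedding of the reactant pattern
  yields one product; bonds between mapped atoms that the pattern does not
  mention are preserved. Because a SMARTS component separator does not
  *forbid* a bond between fragments, the pattern engine also returns
  embeddings in which a bond to be created already exists; it then
  overwrites the order and silently refills the lost valence with
  hydrogens. Such products either carry radicals (rejected) or change the
  molecular formula — impossible for a bond rearrangement — so product
  tuples that fail formula conservation are rejected too.
* **Direct bond editing** (`derive.apply_config`) — enumerate ordered
  pairs of bonds with the required orders, check the two created bonds are
  genuinely absent (order exactly as specified), deduplicate embeddings
  equivalent under the rule's own label symmetries, and edit a copy of the
  graph. This is the engine's default for derived rules; it avoids the
  quadratic blow-up of generic matching on large hydrogen-explicit graphs
  (roughly an order of magnitude faster at C12).

Aromatic inputs are kekulized before either route; the rules operate on
integer Kekulé bond orders and no aromaticity model is configurable.

## Distance calculus and iteration bounds

For two isomers on a fixed shared atom indexing (explicit hydrogens
included), S = Σ_{i<j} |a_ij − b_ij| is the labeled bond-order distance —
always even, zero exactly at identity, and at most 3(N² − N)/2 for N
atoms. One suitable rule application reduces S by 2 or 4, so any isomer is
reachable in at most S/2 ≤ 3(N² − N)/4 transformations; for alkanes the
acyclic single-bond structure tightens the bound to N − 1 iterations.
`greedy_transform` realizes such walks by depth-first search over
distance-reducing applications (greedy descent alone suffices for almost
every pair; backtracking covers rare dead ends), preferring intermediates
that satisfy the structural filters. S is *not* minimized over atom
correspondences — the indexing is fixed, as the bound only needs some
correspondence.

**Known boundary case.** Exhaustive checking of every isomer pair with up
to five heavy atoms (3480 ordered pairs from the brute-force multigraph
oracle) found one unordered pair — C1#CCC#C1 and C1#CC2=C1C2, hydrogen-
depleted structures with triple bonds in or fused to 3-membered rings —
for which *no* monotone distance-reducing walk exists: at some
intermediate state every candidate move matches one of the 8
ring-constraint-excluded configurations. Similarly, the hydrogen-free
all-double-bond 5-ring C1=C=C=C=C=1 satisfies the stated constraints but
is frozen: every rule application on it violates them, so breadth-first
enumeration can neither reach nor leave it. The universality of the rule
set therefore fails only at such maximally strained, hydrogen-free
extremes, far outside practically relevant chemistry; the tests assert
convergence everywhere else *and* assert this exact counterexample set.

## Canonical augmentation

Growth rules attach one new carbon to a growing skeleton by 1..4 bonds
(`A1`..`A4`); attachment atoms must be pairwise non-adjacent, which is
enforced by rejecting products containing 3-membered rings (the two are
equivalent: a triangle appears exactly when two attachment atoms were
adjacent), so generated skeletons are triangle-free. With `A1` alone the
output is the acyclic (alkane) series; running to `max_atoms` takes
`max_atoms − 1` iterations and the cumulative count at N equals the sum of
the per-N isomer-transformation counts — a cross-algorithm consistency
check the tests enforce up to N = 12.

## Enzymatic rule extraction

Inputs are atom-mapped reaction SMILES with every substrate heavy atom
uniquely mapped (fully unmapped substrate fragments are treated as
spectators and excluded). The reaction center is the set of atom-map pairs
whose bond order differs between the two sides; a reaction with no change
is rejected as degenerate. Each substrate yields one component carrying
the other substrates as fixed co-substrates and the products that share at
least one mapped atom with the focal substrate; the emitted rule is a
multi-component reaction SMARTS, so only the focal substrate varies on
application. Diameter-d truncation keeps the atoms within d/2 bonds
(heavy-atom graph distance) of any center atom; unmapped (created) product
atoms are always kept; kept atoms retain charge, aromaticity and hydrogen
counts verbatim, so smaller diameters yield strictly less constrained —
more promiscuous — patterns. Atom–atom mapping itself is out of scope;
reactions must arrive pre-mapped.

## Screening

`tournament_select` shuffles the merged candidate set into `n_subsets`
subsets (sizes differing by at most one) and keeps the `top_k` best of
each, breaking score ties on the canonical key; the global best always
survives its own subset, making the search elitist and the best-score
trajectory non-decreasing. `inverse_qsar_search` samples one molecule per
iteration (two when bond-rearrangement rules are present, so fragments can
cross between structures; the possibly disconnected product of a
cross-molecule application is split into its component molecules, unlike
in enumeration where disconnected products are discarded), fires the
rules, scores products with the user's scorer (deterministic
molecule → activity, higher is better; failures drop the product with a
warning), and tournament-selects the next population. All randomness flows
from one seeded NumPy generator. Because sampling is random, reaching an
optimum needs a modest iteration budget: on the toy landscape (grow from
ethane toward eight heavy atoms, scorer = −|heavy atoms − 8|) seeds 1–7
reach the optimum within 6–22 iterations; tests allow 40.

Defaults follow the screening literature on this engine: 10 subsets × top
10 (population cap 100), MACCS-key Tanimoto similarity with thresholds
0.5 (broad) or 0.8 (close analogs).

## Mass annotation

Monoisotopic masses come from the standard isotope table (most abundant
isotope per element, hydrogens included). A (molecule, adduct) pair is
assigned to a peak when |m/z_obs − m/z_theo|/m/z_theo ≤ tol, with
m/z_theo = (M + shift)/|z|; the default tolerance is 5 ppm and the default
mode negative, matching common Orbitrap metabolomics practice. The shipped
adduct lists ([M−H]−, [M+Cl]− / [M+H]+, [M+Na]+) are package defaults, not
a reference set; both are configurable. Coverage (fraction of peaks with
≥1 candidate) and the median/mean number of distinct candidate compounds
per *assigned* peak summarize a candidate set's explanatory power; both
are non-decreasing in the tolerance and in the candidate set. Isotope
patterns, MS/MS fragmentation and retention time are out of scope.

## Synthetic fixtures and oracles

Everything needed for testing is generated programmatically
(`rxnspace.fixtures`): linear alkane seeds C1–C14; two hand-built mapped
toy reactions — a bimolecular amine/alcohol exchange whose center is
exactly two broken and two formed single bonds (a transaminase-style
center without multi-order bookkeeping, given a heptan-2-ol tail so that
diameters 2–10 truncate differently) and a unimolecular cyclopropane ring
opening; a panel of alcohols sharing successively less of the native
substrate's context; and two synthetic scorers (heavy-atom-count target;
MACCS similarity to a reference). These fixtures emulate the *mechanics*
of enzymatic data — mapped centers, co-substrates, promiscuity — not its
scale or chemical diversity: passing tests demonstrate the contracts of
the algorithms, not coverage of any real metabolome or QSAR.

Two independent oracles cross-check the engine: non-isomorphic free-tree
enumeration (networkx) for the alkane series, and exhaustive recursive
enumeration of connected carbon multigraphs (orders ≤ 3, valence ≤ 4,
small-ring rule) for the distance calculus. Problem sizes in the default
test run — alkanes to N = 12, augmentation to N = 14, exhaustive pairs to
five heavy atoms — keep the suite at a few minutes on one CPU while still
hitting every published count they reproduce.
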