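# rxnspace

Rule-based exploration of chemical space: a breadth-first engine that fires
reaction SMARTS rules on a set of source molecules, plus everything needed
to use it for structural isomer enumeration, enzymatic reaction-rule
extraction, stochastic inverse-QSAR screening, and metabolite peak
annotation.

## The problem

Network-generation tools for synthesis planning and metabolic engineering
share one core loop: apply a set of reaction rules to a *source* set of
compounds, sanitize and deduplicate the products, and promote everything
not yet seen (tracked in a *sink* set) to the next iteration. With the
right rules, the same loop enumerates molecules rather than pathways.
`rxnspace` provides that loop as a library and CLI, together with:

* **Canonical augmentation** — grow carbon skeletons one atom per
  iteration from a single unbonded carbon; with the single-bond attachment
  rule every product is an acyclic skeleton (an alkane).
* **Isomer transformation** — start from one hydrogen-saturated molecule
  and apply valence-conserving bond rearrangements until no new
  constitutional isomer appears. The minimal rearrangement touches four
  atoms: delete bonds 1–2 and 3–4, create 2–3 and 1–4, each by one order,

      b12 = a12 − 1,  b23 = a23 + 1,  b34 = a34 − 1,  b14 = a14 + 1,

  which conserves every atom's total bond order. Solvability forces
  a12, a34 ∈ {1,2,3} and a14, a23 ∈ {0,1,2} — 81 configurations — and
  symmetry (a14 ≥ a23, a12 ≥ a34), the maximal valence of 4, and the
  exclusion of two double bonds on one atom of a 3- or 4-membered ring
  reduce these to 36, 27, and finally **19 distinct rules**
  (`rxnspace.derive` re-derives them from scratch and emits each as a
  reaction SMARTS). The sum S of absolute bond-order differences between
  two isomers drops by 2 or 4 per application, giving an iteration bound
  of 3(N² − N)/4 in general and N − 1 for alkanes.
* **Variable-diameter enzymatic rules** — given an atom-mapped reaction,
  locate the reaction center (bonds whose order changes), split the
  reaction into one component per substrate, and truncate each component
  to the atoms within d/2 bonds of the center for each even diameter d in
  2..16 (∞ keeps the full component). Smaller diameters give more
  promiscuous rules.
* **Inverse-QSAR screening** — sample molecules from a population, fire
  the rules, score products with a pluggable scorer, and keep the top 10
  of each of 10 random subsets of the merged population (elitist
  tournament selection), plus MACCS/Tanimoto similarity filtering.
* **Mass annotation** — monoisotopic masses and adduct-aware assignment of
  candidate compounds to m/z peaks within a ppm tolerance, with per-peak
  coverage statistics.

## Worked example

Enumerate the constitutional isomers of decane with the single-bond
transformation rule:

```bash
rxnspace derive-rules --output rules.csv
rxnspace enumerate-transform --seed CCCCCCCCCC --rules rules.csv --output decane_isomers.csv
```

prints

```
iteration 1: 7 new structures
iteration 2: 23 new structures
iteration 3: 27 new structures
iteration 4: 15 new structures
iteration 5: 2 new structures
iteration 6: 0 new structures
75 structures in 6 iterations (last novelty at iteration 5) -> decane_isomers.csv
```

— the 75 constitutional isomers of C10H22, with the sixth breadth-first
round confirming closure. (The full 19-rule file and the single-bond rule
R1 alone give the same answer here: the formula C10H22 leaves no room for
rings or multiple bonds, and products that expel H2 are disconnected and
filtered.) The same numbers come from the library:

```python
from rxnspace import derive_rules, enumerate_isomers, parse_molecule

r1 = [r for r in derive_rules() if r.rule_id == "R1"]
result = enumerate_isomers(parse_molecule("CCCCCCCCCC"), r1)
print(len(result.structures), result.n_iterations)   # 75 6
```

Growing skeletons instead (`rxnspace enumerate-augment --max-atoms 10
--output aug.csv`) yields 150 cumulative structures — the sum of the
isomer counts for 1..10 carbons, as the two algorithms must agree.

Other subcommands: `extract-rules` (mapped reactions → diameter rule
series), `screen` (tournament search; writes a best/mean score
trajectory), `annotate-masses` (peak assignment), `fixtures` (the bundled
deterministic toy inputs).

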