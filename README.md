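# mixfiles

Machine-readable chemical mixtures: hierarchical **Mixfile** documents,
**MInChI** (Mixtures InChI) notation generation and analysis, and
rule-based extraction of mixtures from catalog-style text.

Single-structure cheminformatics has the Molfile and the InChI; most real
laboratory substances, however, are mixtures — a reagent with a purity
estimate, butyllithium dissolved in "hexanes" (itself a mixture of C6
isomers), a drug tablet with one active and many inactive ingredients.
`mixfiles` is for chemists, inventory systems and cheminformatics
pipelines that need to record *what is in the bottle* — components, their
structures and their concentrations, at any level of nesting and with any
amount of missing information — and to search and compare those records
with plain string operations.

## The data model and notation

A **Mixfile** is a JSON tree. Every node is a component with optional
fields in five groups: *name* (`name`, `description`, `synonyms`),
*structure* (`molfile` as the primary record, with `formula`/`inchi`/
`inchiKey`/`smiles` as transient derived properties), *concentration*
(`quantity` as a point value or `[low, high]` range, `relation`, `ratio`,
`units`), *references* (`identifiers`, `links`) and *sub-components*
(`contents`). A component with no concentration is by convention the
implied remainder of its mixture. Fifteen standard units are supported,
each mapped to a Units Ontology URI and a MInChI shorthand code with a
scale factor (e.g. mol/L, mmol/L and μmol/L all scale onto the molarity
code `mr`).

A **MInChI** string flattens a mixture into a single ASCII line:

```
MInChI=0.00.1S/<components>/n<indexing>/g<concentration>
```

The component layer is the sorted, deduplicated set of prefix-stripped
InChI identifiers joined by `&`; the indexing layer mirrors the tree with
curly braces, giving each structure-bearing node its 1-based component
index; the concentration layer repeats the same brace skeleton with one
compact token per node (`1.9:2.1mr`, `>=97pp`, `2vp`, or blank). Because
the notation is pure text, containment, shared-ingredient detection and
even concentration equivalence — via the molecular formula that opens
every InChI — need no chemistry engine.

## Worked example

```python
from mixfiles import (assemble_minchi, compare_mixtures, extract_mixture,
                      make_fixture, mass_to_molar)

# assemble MInChI for a formaldehyde/water mixture
print(assemble_minchi(make_fixture("methods_formaldehyde_water")))
# MInChI=0.00.1S/CH2O/c1-2/h1H2&H2O/h1H2/n{1&2}/g{&}

# extract a vendor-catalog line into a mixture tree
mix = extract_mixture("Trimethyl(trifluoromethyl)silane solution 2 M in THF")
print([(c.name, c.quantity) for c in mix.root.contents])
# [('Trimethyl(trifluoromethyl)silane', Quantity(value=2, relation=None, ratio=None, units='mol/L')),
#  ('tetrahydrofuran', None)]

# compare dimethylamine at 90 g/L with dimethylamine at 1.9-2.1 mol/L
print(mass_to_molar(90, "g/L", "C2H7N"))
# 1.9962293445713652
report = compare_mixtures(
    assemble_minchi(make_fixture("fig14a_dimethylamine_90gL")),
    assemble_minchi(make_fixture("fig14b_dimethylamine_2M")))
print(report.shared_count, report.shared[0].verdict)
# 1 compatible
```

90 g/L of dimethylamine (formula `C2H7N`, molecular weight 45.085 g/mol)
is 1.996 mol/L — inside the second mixture's 1.9–2.1 mol/L range, so the
two products share a common ingredient at a common concentration in
different solvents.

The same operations are available from a shell:

```sh
mixfile minchi --fixture fig13a_caffeine
mixfile parse-text "1-Aza-12-crown-4 ≥ 97.0%"
mixfile compare <minchi-or-path> <minchi-or-path>
mixfile validate my_mixture.mixfile
```

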