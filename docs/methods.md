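# Methods

## The Mixfile model

A mixture is a rooted ordered tree of components. The root is itself a
component (a single-substance mixture with a purity is just a root with a
structure and a quantity; a solution is a blank root with children), with
one extra top-level JSON key, `mixfileVersion: 1.0`. Components carry five
optional field groups — name, structure, concentration, references,
sub-components — and the format makes *absence* meaningful: a missing
quantity denotes the implied remainder of the mixture, and a node with a
name but no structure is a legitimate description of a substance that has
no molecular representation (commercial solvent blends, tars, polymers).

Two modelling rules are enforced rather than assumed:

- **Derived identifiers are transient.** `formula`, `inchi`, `inchiKey`
  and `smiles` are properties of the `molfile`. `normalize_derived_fields`
  recomputes them through a pluggable `StructureBackend` (an RDKit
  implementation is included) or, with no backend available, erases them —
  a stale identifier is worse than none. The one exception: identifier
  fields on a node *without* a molfile are primary data and are kept.
- **Unknown keys round-trip.** Unrecognized fields (including
  underscore-prefixed private extensions) are preserved verbatim in an
  `extras` map, so this implementation can pass through documents written
  by richer tools.

Validation separates hard errors (reversed ranges, unknown units or
relations, non-positive ratio denominators, a value and a ratio on the
same component, a value with no units) from warnings (a non-root node with
no name, structure or children). Serialization refuses documents with hard
errors and is canonical: fixed key order, two-space indent, shortest
round-trip float formatting — so serializing twice is byte-identical and
`parse ∘ serialize` is the identity on the data model.

## Units and concentration arithmetic

The 15-row unit table (common name, Units Ontology URI, two-letter MInChI
code, scale factor) is shipped as a JSON resource (`mixfiles/data/
units.json`) and loaded at import, so external tools can audit the exact
table this package applies. `μ` is canonical in unit names; ASCII `u` is
accepted on input. Translation to MInChI multiplies the value (or both
range ends) by the scale factor; ratios emit only the numerator under the
`vp` code, the denominator being implied by the sibling set — which also
means the denominator is not recoverable from MInChI alone.

Molecular weights are computed from a hardcoded table of IUPAC 2021
standard atomic weights (conventional values; most-stable-isotope masses
for elements without stable isotopes). Formula parsing accepts the
multi-part formulas of disconnected InChIs (`3C2H5.Al`) but ignores
charge and isotope labels. The mass↔molar bridge converts g/L-family
values to mol/L by dividing by the molecular weight; temperature- and
density-dependent conversions (w/w% ↔ molarity) are out of scope because
they need data a mixture record does not carry.

## MInChI generation

Assembly builds three layers. Components: every node's InChI, prefix
stripped, collected into a set, sorted lexicographically and joined with
`&`; a node with a molfile but no InChI raises an error naming the node
path instead of silently dropping a component. Indexing and concentration:
one recursive traversal emits both layers in the same order — children's
blocks first, wrapped in `{}` and joined by `&`, then the node's own
component index (empty for structureless nodes) and concentration token —
so the two layers always share a brace skeleton. A childless root emits no
braces (the singleton case), and a node carrying both a structure and
children appends its index after its children's block.

Numeric choices where the notation's prose leaves the dialect open:

- Tokens render numbers as shortest round-trip decimals, switching to
  `e±N` exponent form only for magnitudes ≥ 1e6 or < 1e-3; ranges join
  the two scaled values with `:`.
- Relations other than `=` are prefixed verbatim (`>=97pp`, `~5mf`);
  `=` is omitted.
- Sibling subtree blocks are emitted in lexicographic order of their
  indexing-layer text, giving a canonical branch ordering that is
  independent of the order components were entered in the source
  document (ties between identical index texts are broken by input
  order).
- The emitted prefix is `MInChI=0.00.1S` with no whitespace.

Splitting locates `/g` and then `/n` from the right; neither trailing
layer may contain `/` and no standard InChI layer uses those letters, so
the markers are unambiguous. Splitting checks brace balance and skeleton
equality, and `split ∘ assemble` is lossless on the three layer texts.
Full reconstruction of a Mixfile from a MInChI is deliberately not
attempted: the transformation discards names, references and branch
provenance by design.

## Comparison

Containment is delimiter-bounded by default — a query fragment must equal
one `&`-delimited component entry — because a raw substring scan accepts
proper prefixes/suffixes of longer fragments (`H2O` vs `CH2O/...`); the
simpler indexOf semantics remains available behind a flag. Shared
components are the sorted intersection of the two component sets.
Concentration equivalence parses tokens back into (interval, code): same
code compares directly, a `wv`/`mr` pair is bridged through the molecular
weight taken from the fragment's own formula layer, and any other code
pair is incompatible. Intervals are compared by overlap with a relative
slack of `rel_tol × max(|high_a|, |high_b|)`, which reduces to
`|a−b| ≤ rel_tol·max(a,b)` for two points. The default `rel_tol` of 5%
absorbs nominal-vs-computed gaps (1.996 mol/L vs a "2 M" label) without
conflating genuinely different strengths; relation prefixes are ignored in
the numeric comparison. When a shared fragment occurs at several tree
positions, all positions' tokens are considered and the verdict is
`compatible` if any pair agrees.

## Text extraction

Extraction is a recursive pipeline per node: regex rules to fixpoint, then
the lookup table, then an optional name resolver. Four rule kinds exist —
remove, replace, concentration (move a matched span into the quantity
fields) and branch (split the name at a separator into child components,
each recursively processed). Rules run in priority order, restarting after
every change, with a bounded pass count (32) guarding against rule sets
that oscillate. Every firing can be recorded in an audit log, which is
also how the conservation property is tested: each input character either
survives in a node name, is captured as a quantity, or was deleted by a
logged firing.

The shipped starter set handles the common vendor-catalog shapes: a
`{solute} in {solvent}` branch rule whose separator must lie outside
parentheses (guarding the very short keyword "in" against names like
`poly(styrene in block)`), a quantity recognizer covering relations
(`≥ ≤ ~ > <`), ranges (`1.9–2.1`), and unit spellings including the
molar shorthand (`M` → mol/L, `mM` → mmol/L), a deletion rule for the
superfluous word "solution", and whitespace/punctuation tidying. The
lookup table resolves common solvent names and abbreviations to bundled
structures and expands the classic mixture-valued names — `hexanes` to
four C6 isomers, `xylenes` to the three ring isomers — by replacing the
component with a subtree while keeping its quantity. Rule sets and tables
are plain Python data and can be supplied per call; name-to-structure
conversion itself (OPSIN's role) is exposed only as the `NameResolver`
contract, so the package runs fully offline.

This is a deliberately conservative extractor: it is deterministic,
auditable and precise on the catalog grammar it models, and it leaves
anything it cannot interpret as a name-only node rather than guessing.
It does not attempt free-paragraph text, nested parenthesized recipes, or
statistical name recognition.

## Fixtures and the random-document generator

`make_fixture` reconstructs thirteen canonical example mixtures with
structure identifiers frozen as literals (computed once with RDKit
2024.09), so tests need no chemistry engine. Where a source example leaves
a number unstated, a commercially typical value was chosen once and
documented on the fixture (tert-butyllithium 1.7 mol/L, neat OsO4 ≥ 98%,
aqueous OsO4 4 w/w%, caffeine ≥ 99%, BBr3 1 mol/L, a 9:1
Markovnikov isomer ratio); the two dimethylamine solvents (methanol, THF)
are likewise synthetic stand-ins — distinct solvents, which is all the
comparison exercises. The lithium diisopropylamide fixture encodes only
the documented constraints (multi-level solvent branch, three
structureless nodes, molarity on the active ingredient, ratios within the
solvent branch).

`random_mixfile(seed, max_depth=3, max_children=3)` grows a seeded tree
whose structures come from the bundled compound registry and whose
quantities cover all 15 units, point values, ranges, ratios, relations and
the implied-remainder case, plus occasional private `_`-prefixed extras.
It emulates the *structural* variety of real mixture documents — nesting,
duplicate ingredients, structureless containers, missing data — not
chemical plausibility: concentrations are not made to sum sensibly and
structures are drawn independently. Passing property tests therefore
certify serialization and notation invariants, not chemical validity of
generated compositions.

Property tests and the acceptance script run these invariants over 1000
seeds (documents of ≤ ~40 nodes), which completes in about a second;
the sizes are chosen to exercise deep nesting and duplicates, not bulk.

## Known limitations

- Molfile payloads are opaque strings; no V3000, query-feature or polymer
  handling, and no structure perception beyond what a backend provides.
- MInChI concentration tokens for `vp` lose the ratio denominator, so a
  parsed ratio cannot be renormalized without the sibling context.
- The extractor's rule set is a starter grammar; coverage of a real
  vendor catalog requires site-specific rules and lookup entries.
- Unit conversions requiring density or temperature are not provided.
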