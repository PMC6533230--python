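"""Worked-example mixtures and a seeded random-document generator.

``make_fixture`` reconstructs the canonical example mixtures — reagent
catalog staples like butyllithium in "hexanes" or dimethylamine solutions
— with structure identifiers embedded as frozen literals, so nothing here
needs a chemistry engine. Where a figure's text leaves a number
unspecified (e.g. the purity of neat osmium tetroxide), a commercially
typical value was chosen once and is documented on the fixture.

``random_mixfile`` produces reproducible random-but-valid documents for
property tests: every quantity draws from the standard unit table and
every structure from the bundled compound registry.
"""

from __future__ import annotations

import random

from .compounds import names as compound_names
from .compounds import structure_payload
from .errors import MixfileError
from .model import MixComponent, Mixfile, Quantity

__all__ = ["FIXTURE_KEYS", "make_fixture", "random_mixfile"]


def _comp(name=None, quantity=None, contents=None, structure=None, **kw) -> MixComponent:
    fields = dict(structure_payload(structure)) if structure else {}
    if name is not None:
        fields["name"] = name
    node = MixComponent(quantity=quantity, contents=contents or [], **fields, **kw)
    return node


def _hexanes(quantity=None) -> MixComponent:
    # the four major C6 isomers of the commercial solvent; vendor
    # compositions vary and proportions are typically unstated
    return _comp(
        "hexanes",
        quantity=quantity,
        contents=[
            _comp(structure="n-hexane"),
            _comp(structure="2-methylpentane"),
            _comp(structure="3-methylpentane"),
            _comp(structure="methylcyclopentane"),
        ],
    )


def _fig1() -> Mixfile:
    """Single known component with a purity estimate: ≥ 97%."""
    return Mixfile(root=_comp(
        structure="(S)-3-butene-1,2-diol",
        quantity=Quantity(value=97, relation=">=", units="%"),
    ))


def _fig2() -> Mixfile:
    """Active ingredient (triethylaluminium, 2 molar) dissolved in
    toluene, whose blank concentration means "remainder". The source
    figure's caption and body text disagree on the alkyl group; the body
    text's triethylaluminium is used."""
    return Mixfile(root=MixComponent(contents=[
        _comp(structure="triethylaluminium", quantity=Quantity(value=2, units="mol/L")),
        _comp(structure="toluene"),
    ]))


def _fig3() -> Mixfile:
    """n-Butyllithium dissolved in "hexanes", itself a mixture of four C6
    isomers of unspecified proportions."""
    return Mixfile(root=MixComponent(contents=[
        _comp(structure="n-butyllithium"),
        _hexanes(),
    ]))


def _fig4() -> Mixfile:
    """tert-Butyllithium in pentane (1.7 mol/L is the common commercial
    strength; the source states no number)."""
    return Mixfile(root=MixComponent(contents=[
        _comp(structure="tert-butyllithium", quantity=Quantity(value=1.7, units="mol/L")),
        _comp(structure="pentane"),
    ]))


def _fig5() -> Mixfile:
    """Markovnikov bromination product: 2-bromopropane as the major
    isomer with relative proportions as ratios (9:10 vs 1:10 chosen as a
    typical outcome; the source states no number)."""
    return Mixfile(root=MixComponent(contents=[
        _comp(structure="2-bromopropane", quantity=Quantity(ratio=[9, 10])),
        _comp(structure="1-bromopropane", quantity=Quantity(ratio=[1, 10])),
    ]))


def _fig6a() -> Mixfile:
    """Neat (mostly pure) osmium tetroxide; ≥ 98% purity chosen as a
    typical catalog value."""
    return Mixfile(root=_comp(
        structure="osmium tetroxide",
        quantity=Quantity(value=98, relation=">=", units="%"),
    ))


def _fig6b() -> Mixfile:
    """Dilute aqueous osmium tetroxide solution (4 w/w% is a common
    commercial form)."""
    return Mixfile(root=MixComponent(contents=[
        _comp(structure="osmium tetroxide", quantity=Quantity(value=4, units="w/w%")),
        _comp(structure="water"),
    ]))


def _fig13a() -> Mixfile:
    """Caffeine with a purity estimate — the MInChI singleton example."""
    return Mixfile(root=_comp(
        structure="caffeine",
        quantity=Quantity(value=99, relation=">=", units="%"),
    ))


def _fig13b() -> Mixfile:
    """Boron tribromide dissolved in methylene chloride; the solvent's
    concentration is blank (implied remainder). 1 mol/L is the common
    commercial strength."""
    return Mixfile(root=MixComponent(contents=[
        _comp(structure="boron tribromide", quantity=Quantity(value=1, units="mol/L")),
        _comp(structure="dichloromethane"),
    ]))


def _fig13c() -> Mixfile:
    """Lithium diisopropylamide in a multi-level solvent mixture: overall
    molarity on the active ingredient, ratio proportions inside the
    solvent branch, and three structureless container nodes (the root,
    the solvent node and "hexanes"). Encodes only what the source body
    text states; the full composition appears only in a figure."""
    return Mixfile(root=MixComponent(contents=[
        _comp(structure="lithium diisopropylamide", quantity=Quantity(value=2, units="mol/L")),
        _comp("solvents", contents=[
            _comp(structure="tetrahydrofuran", quantity=Quantity(ratio=[1, 2])),
            _hexanes(quantity=Quantity(ratio=[1, 2])),
        ]),
    ]))


def _fig14a() -> Mixfile:
    """Dimethylamine at 90 g/L. The solvent is not named in the source
    body text; methanol (a common commercial form) is a synthetic
    stand-in chosen here."""
    return Mixfile(root=MixComponent(contents=[
        _comp(structure="dimethylamine", quantity=Quantity(value=90, units="g/L")),
        _comp(structure="methanol"),
    ]))


def _fig14b() -> Mixfile:
    """Dimethylamine between 1.9 and 2.1 mol/L in a different solvent
    (THF — a synthetic stand-in, as for the 90 g/L form)."""
    return Mixfile(root=MixComponent(contents=[
        _comp(structure="dimethylamine", quantity=Quantity(value=[1.9, 2.1], units="mol/L")),
        _comp(structure="tetrahydrofuran"),
    ]))


def _formaldehyde_water() -> Mixfile:
    """The MInChI assembly worked example: a blank root with formaldehyde
    and water children and no concentrations."""
    return Mixfile(root=MixComponent(contents=[
        _comp(structure="formaldehyde"),
        _comp(structure="water"),
    ]))


_FIXTURES = {
    "fig1_butenediol": _fig1,
    "fig2_alkylaluminium": _fig2,
    "fig3_nBuLi_hexanes": _fig3,
    "fig4_tBuLi_pentane": _fig4,
    "fig5_bromopropane_isomers": _fig5,
    "fig6a_OsO4_neat": _fig6a,
    "fig6b_OsO4_solution": _fig6b,
    "fig13a_caffeine": _fig13a,
    "fig13b_BBr3_DCM": _fig13b,
    "fig13c_LDA": _fig13c,
    "fig14a_dimethylamine_90gL": _fig14a,
    "fig14b_dimethylamine_2M": _fig14b,
    "methods_formaldehyde_water": _formaldehyde_water,
}

FIXTURE_KEYS = tuple(sorted(_FIXTURES))


def make_fixture(key: str) -> Mixfile:
    """Build one named worked-example mixture; raises on unknown keys."""
    try:
        builder = _FIXTURES[key]
    except KeyError:
        raise MixfileError(f"unknown fixture {key!r}; known: {', '.join(FIXTURE_KEYS)}") from None
    return builder()


# ---------------------------------------------------------------------------
# random documents for property testing

_POINT_UNITS = ["%", "w/v%", "w/w%", "v/v%", "mol/mol%", "mol/L", "mmol/L",
                "μmol/L", "nmol/L", "pmol/L", "g/L", "mg/L", "μg/L", "mol/kg"]
_RELATIONS = [None, "=", "~", "<", "<=", ">", ">="]


def _random_quantity(rng: random.Random) -> Quantity | None:
    kind = rng.randrange(4)
    if kind == 0:
        return None  # implied remainder
    if kind == 1:
        num = rng.randint(1, 9)
        return Quantity(ratio=[num, num + rng.randint(0, 9)])
    units = rng.choice(_POINT_UNITS)
    relation = rng.choice(_RELATIONS)
    value = round(rng.uniform(0.01, 99.0), rng.randrange(4))
    if kind == 3:
        high = round(value + rng.uniform(0.01, 10.0), 3)
        return Quantity(value=[value, high], relation=relation, units=units)
    return Quantity(value=value, relation=relation, units=units)


def _random_component(rng: random.Random, depth: int, max_depth: int, max_children: int) -> MixComponent:
    node = MixComponent()
    if rng.random() < 0.75:
        node = MixComponent(**structure_payload(rng.choice(compound_names())))
    elif rng.random() < 0.8:
        node.name = f"substance-{rng.randint(1, 999)}"
    node.quantity = _random_quantity(rng)
    if depth < max_depth and rng.random() < 0.5:
        n = rng.randint(0, max_children)
        node.contents = [
            _random_component(rng, depth + 1, max_depth, max_children) for _ in range(n)
        ]
    if rng.random() < 0.2:
        node.extras["_note"] = f"generated-{rng.randint(0, 9999)}"
    return node


def random_mixfile(seed: int, max_depth: int = 3, max_children: int = 3) -> Mixfile:
    """Seeded random valid Mixfile: same seed, same tree."""
    rng = random.Random(seed)
    root = _random_component(rng, 0, max_depth, max_children)
    return Mixfile(root=root)
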