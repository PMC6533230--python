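"""Rule-based text-to-mixture extraction."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mixfiles import (
    ExtractionRule,
    LookupEntry,
    MixComponent,
    Quantity,
    RuleCycleError,
    apply_rules,
    default_lookup_table,
    default_rules,
    extract_mixture,
    lookup_name,
    parse_concentration_text,
)
from mixfiles.compounds import inchi_of


class TestParseConcentrationText:
    @pytest.mark.parametrize(
        "span, expected",
        [
            ("≥ 97.0%", Quantity(value=97.0, relation=">=", units="%")),
            ("2 M", Quantity(value=2, units="mol/L")),
            ("~0.5 mM", Quantity(value=0.5, relation="~", units="mmol/L")),
            ("90 g/L", Quantity(value=90, units="g/L")),
            ("1.9–2.1 mol/L", Quantity(value=[1.9, 2.1], units="mol/L")),
            ("<= 5 w/w%", Quantity(value=5, relation="<=", units="w/w%")),
        ],
    )
    def test_recognized_spans(self, span, expected):
        assert parse_concentration_text(span) == expected

    @pytest.mark.parametrize("span", ["banana", "", "Mg alloy", "in THF"])
    def test_no_match_returns_none(self, span):
        assert parse_concentration_text(span) is None


class TestApplyRules:
    def test_branch_splits_solute_and_solvent(self):
        node = MixComponent(name="Trimethyl(trifluoromethyl)silane solution 2 M in THF")
        apply_rules(node, [ExtractionRule("branch", r"\s+in\s+", name="in")])
        assert node.name is None
        assert [c.name for c in node.contents] == [
            "Trimethyl(trifluoromethyl)silane solution 2 M",
            "THF",
        ]

    def test_concentration_then_removal_leaves_bare_name(self):
        node = MixComponent(name="Trimethyl(trifluoromethyl)silane solution 2 M")
        apply_rules(node, default_rules())
        assert node.name == "Trimethyl(trifluoromethyl)silane"
        assert node.quantity == Quantity(value=2, units="mol/L")

    def test_branch_keyword_inside_parentheses_is_ignored(self):
        node = MixComponent(name="poly(styrene in block) resin")
        apply_rules(node, [ExtractionRule("branch", r"\s+in\s+", name="in")])
        assert node.contents == []
        assert node.name == "poly(styrene in block) resin"

    def test_unmatched_node_unchanged(self):
        node = MixComponent(name="gelatinous coal tar")
        apply_rules(node, default_rules())
        assert node.name == "gelatinous coal tar"
        assert node.quantity is None and node.contents == []

    def test_oscillating_replace_rules_hit_cycle_guard(self):
        rules = [
            ExtractionRule("replace", r"^alpha$", "beta", priority=1),
            ExtractionRule("replace", r"^beta$", "alpha", priority=2),
        ]
        with pytest.raises(RuleCycleError):
            apply_rules(MixComponent(name="alpha"), rules)


class TestLookup:
    def test_abbreviation_resolves_to_structure(self):
        entry = lookup_name("THF", default_lookup_table())
        assert entry.structure["name"] == "tetrahydrofuran"
        assert entry.structure["inchi"] == inchi_of("tetrahydrofuran")

    def test_xylenes_subtree_enumerates_three_isomers(self):
        entry = lookup_name("xylenes", default_lookup_table())
        assert entry.subtree is not None
        assert [c.name for c in entry.subtree.contents] == ["o-xylene", "m-xylene", "p-xylene"]

    def test_hexanes_subtree_has_four_components(self):
        entry = lookup_name("hexanes", default_lookup_table())
        assert len(entry.subtree.contents) == 4

    def test_case_insensitive_with_whitespace_collapse(self):
        assert lookup_name("  thf ", default_lookup_table()) is not None

    def test_miss_returns_none(self):
        assert lookup_name("unobtainium", default_lookup_table()) is None


class TestExtractMixture:
    def test_name_with_purity_estimate(self):
        mix = extract_mixture("1-Aza-12-crown-4 ≥ 97.0%")
        assert mix.root.contents == []
        assert mix.root.name == "1-Aza-12-crown-4"
        assert mix.root.quantity == Quantity(value=97.0, relation=">=", units="%")

    def test_solute_in_solvent(self):
        mix = extract_mixture("Trimethyl(trifluoromethyl)silane solution 2 M in THF")
        assert len(mix.root.contents) == 2
        solute, solvent = mix.root.contents
        assert solute.name == "Trimethyl(trifluoromethyl)silane"
        assert solute.quantity == Quantity(value=2, units="mol/L")
        assert solvent.name == "tetrahydrofuran"
        assert solvent.inchi == inchi_of("tetrahydrofuran")

    def test_unresolvable_text_stays_name_only(self):
        mix = extract_mixture("gelatinous coal tar")
        assert mix.root.name == "gelatinous coal tar"
        assert not mix.root.has_structure and mix.root.contents == []

    def test_subtree_entry_overwrites_but_keeps_quantity(self):
        mix = extract_mixture("caffeine 5 g/L in hexanes")
        solvent = mix.root.contents[1]
        assert solvent.name == "hexanes"
        assert len(solvent.contents) == 4
        assert solvent.quantity is None

    def test_resolver_is_consulted_after_table(self):
        class Resolver:
            def resolve(self, name):
                if name == "benzene-d6":
                    return {"name": "benzene-d6", "inchi": "InChI=1S/C6D6"}
                return None

        mix = extract_mixture("2 M something odd in benzene-d6", resolver=Resolver())
        assert mix.root.contents[1].inchi == "InChI=1S/C6D6"

    def test_resolver_failure_is_swallowed(self):
        class Exploding:
            def resolve(self, name):
                raise RuntimeError("backend down")

        mix = extract_mixture("mystery sludge", resolver=Exploding())
        assert mix.root.name == "mystery sludge"

    def test_determinism(self):
        text = "Trimethyl(trifluoromethyl)silane solution 2 M in THF"
        a = extract_mixture(text)
        b = extract_mixture(text)
        assert a == b

    def test_empty_text_rejected(self):
        with pytest.raises(ValueError):
            extract_mixture("   ")


@settings(max_examples=60, deadline=None)
@given(st.text(alphabet=st.characters(blacklist_categories=("Cs", "Cc")), min_size=1, max_size=60))
def test_null_case_single_node(text):
    """With empty rules and an empty table, the output is always a single
    node named with the input text."""
    if not text.strip():
        return
    mix = extract_mixture(text, rules=[], table=[])
    assert mix.root.name == text.strip()
    assert mix.root.contents == [] and mix.root.quantity is None


@pytest.mark.parametrize(
    "text",
    [
        "1-Aza-12-crown-4 ≥ 97.0%",
        "Trimethyl(trifluoromethyl)silane solution 2 M in THF",
        "n-Butyllithium solution 2.5 M in hexanes",
        "Osmium tetroxide solution 4 w/w% in water",
        "gelatinous coal tar",
    ],
)
def test_character_conservation(text):
    """Every input character either survives in some node's name, was
    consumed by a concentration capture, or was deleted by an explicit
    remove/replace/branch firing recorded in the audit log."""
    log = []
    mix = extract_mixture(text, table=[], log=log)  # empty table: names untouched by lookup
    surviving = "".join(
        node.name for node, _d, _p in mix.root.walk() if node.name
    )

    def letters(s):
        return sorted(ch for ch in s if not ch.isspace() and ch not in ",;")

    consumed = "".join(f.captured for f in log if f.kind in ("concentration", "branch"))
    # for remove/replace firings, account the difference in length
    removed = "".join(
        f.before for f in log if f.kind in ("remove", "replace")
    )
    kept_after = "".join(
        f.after for f in log if f.kind in ("remove", "replace") and f.after
    )
    # multiset balance: input letters = surviving + concentration captures
    # + (letters deleted by remove/replace rules)
    lhs = letters(text)
    rhs = letters(surviving) + letters(consumed) + [
        c for c in letters(removed) if True
    ]
    # remove/replace firings chain (before -> after), so subtract the kept text
    for ch in letters(kept_after):
        rhs.remove(ch)
    assert sorted(lhs) == sorted(rhs)
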