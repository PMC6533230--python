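"""Mixfile data model: parsing, canonical serialization, validation,
derived-field normalization and tree flattening."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mixfiles import (
    MixComponent,
    Mixfile,
    MixfileParseError,
    MixfileShapeError,
    MixfileValidationError,
    Quantity,
    StructureProps,
    flatten,
    make_fixture,
    normalize_derived_fields,
    parse_mixfile,
    random_mixfile,
    serialize_mixfile,
    validate,
)
from conftest import FIG2_JSON


class TestParse:
    def test_minimal_document(self):
        mix = parse_mixfile('{"mixfileVersion":1.0,"name":"benzene"}')
        assert mix.root.name == "benzene"
        assert mix.root.contents == []
        assert mix.root.quantity is None
        assert mix.version == 1.0

    def test_solution_document_binds_quantity_and_children(self):
        mix = parse_mixfile(FIG2_JSON)
        assert len(mix.root.contents) == 2
        active, solvent = mix.root.contents
        assert active.quantity.value == 2
        assert active.quantity.units == "mol/L"
        assert solvent.quantity is None  # implied remainder

    def test_malformed_json(self):
        with pytest.raises(MixfileParseError):
            parse_mixfile("not json {")

    @pytest.mark.parametrize(
        "doc",
        [
            '{"quantity":[1,2,3],"units":"%"}',
            '{"contents":{"name":"x"}}',
            '{"ratio":[1]}',
            '{"mixfileVersion":"one"}',
        ],
    )
    def test_shape_errors(self, doc):
        with pytest.raises(MixfileShapeError):
            parse_mixfile(doc)

    def test_unknown_fields_land_in_extras(self):
        mix = parse_mixfile('{"name":"x","_privateTag":"kept","customField":[1,2]}')
        assert mix.root.extras == {"_privateTag": "kept", "customField": [1, 2]}


class TestSerialize:
    def test_round_trip_identity_and_idempotence(self, nbuli_hexanes):
        text1 = serialize_mixfile(nbuli_hexanes)
        reparsed = parse_mixfile(text1)
        assert reparsed == nbuli_hexanes
        assert serialize_mixfile(reparsed) == text1  # byte-identical

    def test_private_underscore_field_preserved(self):
        mix = parse_mixfile('{"name":"x","_privateTag":7}')
        out = serialize_mixfile(mix)
        assert json.loads(out)["_privateTag"] == 7

    def test_range_emitted_as_two_element_array(self):
        mix = Mixfile(root=MixComponent(
            name="x", quantity=Quantity(value=[10, 20], units="%")))
        assert json.loads(serialize_mixfile(mix))["quantity"] == [10, 20]

    def test_refuses_invalid_document(self):
        mix = Mixfile(root=MixComponent(
            name="x", quantity=Quantity(value=[20, 10], units="%")))
        with pytest.raises(MixfileValidationError):
            serialize_mixfile(mix)

    def test_unicode_relation_normalized_to_ascii(self):
        mix = parse_mixfile('{"name":"x","quantity":97,"relation":"≥","units":"%"}')
        assert mix.root.quantity.relation == ">="


class TestValidate:
    def test_purity_only_mixture_is_clean(self):
        violations = validate(make_fixture("fig1_butenediol"))
        assert [v for v in violations if v.severity == "error"] == []

    @pytest.mark.parametrize(
        "quantity, fragment",
        [
            (Quantity(value=[20, 10], units="%"), "range reversed"),
            (Quantity(value=5, units="furlong"), "unknown unit"),
            (Quantity(ratio=[1, 0]), "denominator"),
            (Quantity(value=1, ratio=[1, 2], units="%"), "mutually exclusive"),
            (Quantity(value=5), "units are required"),
            (Quantity(value=5, relation="!=", units="%"), "unknown relation"),
        ],
    )
    def test_hard_violations(self, quantity, fragment):
        mix = Mixfile(root=MixComponent(name="x", quantity=quantity))
        hard = [v for v in validate(mix) if v.severity == "error"]
        assert any(fragment in v.message for v in hard)

    def test_blank_child_is_warning_not_error(self):
        mix = Mixfile(root=MixComponent(contents=[MixComponent()]))
        violations = validate(mix)
        assert all(v.severity == "warning" for v in violations)
        assert violations and violations[0].path == "root.contents[0]"


class _FakeBackend:
    def from_molfile(self, molfile):
        return StructureProps(formula="XX", inchi="InChI=1S/XX", inchiKey="KEY", smiles="X")


class _FailingBackend:
    def from_molfile(self, molfile):
        raise ValueError("bad CTAB")


class TestNormalizeDerivedFields:
    def test_backend_recomputes_stale_fields(self):
        mix = Mixfile(root=MixComponent(molfile="fake ctab", inchi="InChI=1S/stale"))
        out = normalize_derived_fields(mix, _FakeBackend())
        assert out.root.inchi == "InChI=1S/XX"
        assert out.root.formula == "XX"
        assert mix.root.inchi == "InChI=1S/stale"  # input untouched

    def test_identifier_without_molfile_is_kept(self):
        mix = Mixfile(root=MixComponent(inchi="InChI=1S/H2O/h1H2"))
        out = normalize_derived_fields(mix, backend=None)
        assert out.root.inchi == "InChI=1S/H2O/h1H2"

    def test_molfile_with_no_backend_erases_derived_fields(self):
        mix = Mixfile(root=MixComponent(molfile="fake ctab", inchi="InChI=1S/stale",
                                        smiles="C", formula="CH4"))
        out = normalize_derived_fields(mix, backend=None)
        assert out.root.inchi is None and out.root.smiles is None and out.root.formula is None
        assert out.root.molfile == "fake ctab"

    def test_backend_failure_erases_and_reports(self):
        mix = Mixfile(root=MixComponent(molfile="garbage", inchi="InChI=1S/stale"))
        seen = []
        out = normalize_derived_fields(mix, _FailingBackend(),
                                       on_error=lambda path, exc: seen.append(path))
        assert out.root.inchi is None
        assert seen == ["root"]

    def test_rdkit_backend_derives_real_identifiers(self):
        rdkit = pytest.importorskip("rdkit")
        from mixfiles.structures import RDKitBackend

        backend = RDKitBackend()
        molfile = backend.molfile_from_smiles("C=O")
        mix = Mixfile(root=MixComponent(molfile=molfile, inchi="InChI=1S/stale"))
        out = normalize_derived_fields(mix, backend)
        assert out.root.inchi == "InChI=1S/CH2O/c1-2/h1H2"
        assert out.root.inchiKey == "WSFSSNUMVMOOMR-UHFFFAOYSA-N"


class TestFlatten:
    def test_nested_solvent_mixture(self, nbuli_hexanes):
        entries = flatten(nbuli_hexanes)
        assert len(entries) == 7  # root + reagent + hexanes + 4 isomers
        root, depth0, path0 = entries[0]
        assert depth0 == 0 and path0 == ()
        isomer_depths = [d for node, d, p in entries if len(p) == 2]
        assert isomer_depths == [2, 2, 2, 2]

    def test_single_node(self):
        assert len(flatten(Mixfile(root=MixComponent(name="x")))) == 1


@settings(max_examples=60, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_round_trip_property(seed):
    """parse ∘ serialize is the identity on any generated valid tree, and
    extras keys survive verbatim."""
    mix = random_mixfile(seed)
    mix.root.extras["x-custom"] = {"a": [1, "two"]}
    text = serialize_mixfile(mix)
    again = parse_mixfile(text)
    assert again == mix
    assert again.root.extras["x-custom"] == {"a": [1, "two"]}


@settings(max_examples=60, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_generator_output_validates(seed):
    mix = random_mixfile(seed)
    assert [v for v in validate(mix) if v.severity == "error"] == []
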