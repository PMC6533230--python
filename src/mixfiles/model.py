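"""Data model, JSON (de)serialization, validation and tree utilities for
Mixfile documents.

A Mixfile describes a chemical mixture as a tree. Every node (component)
may carry a name, a structure (a Molfile CTAB V2000 payload plus derived
identifiers), a concentration, database references and an ordered list of
child components. All fields are optional: a component with no
concentration is, by convention, the *implied remainder* of its mixture,
and a component with neither structure nor children is described by name
only.

The JSON dialect is deliberately flat: the root of the document is itself
a component, with one extra top-level key ``mixfileVersion``. Quantity
information lives in four sibling keys on the component
(``quantity``/``relation``/``ratio``/``units``); in memory they are grouped
into a single :class:`Quantity`. Unknown keys are kept verbatim in an
``extras`` map so that private extensions (conventionally named with a
leading underscore) survive a round trip.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Any, Callable, Iterator, Optional, Protocol, Union

from .errors import MixfileParseError, MixfileShapeError, MixfileValidationError

CURRENT_VERSION = 1.0

#: Accepted relation tokens, after normalization to ASCII.
RELATIONS = ("=", "~", "<", "<=", ">", ">=")

#: Unicode relation spellings accepted on input.
_RELATION_ALIASES = {"≥": ">=", "≤": "<=", "≈": "~", "=<": "<=", "=>": ">="}

Number = Union[int, float]


def normalize_relation(rel: str) -> str:
    """Map unicode relation symbols (``≥``, ``≤``, ``≈``) to their ASCII
    forms; ASCII tokens pass through unchanged."""
    return _RELATION_ALIASES.get(rel, rel)


@dataclass
class Quantity:
    """Concentration of one component.

    ``value`` is either a point value or a two-element ``[low, high]``
    range. ``ratio`` is a ``[numerator, denominator]`` pair and is mutually
    exclusive with ``value``. ``units`` must name one of the 15 standard
    units when a value is present; a pure ratio carries no units.
    """

    value: Optional[Union[Number, list]] = None
    relation: Optional[str] = None
    ratio: Optional[list] = None
    units: Optional[str] = None

    def __post_init__(self) -> None:
        if self.relation is not None:
            self.relation = normalize_relation(self.relation)
        if isinstance(self.value, tuple):
            self.value = list(self.value)
        if isinstance(self.ratio, tuple):
            self.ratio = list(self.ratio)

    @property
    def is_range(self) -> bool:
        return isinstance(self.value, list)

    @property
    def is_empty(self) -> bool:
        return self.value is None and self.ratio is None


# Known component keys, in canonical serialization order.
_NAME_FIELDS = ("name", "description", "synonyms")
_STRUCTURE_FIELDS = ("molfile", "formula", "inchi", "inchiKey", "smiles")
_QUANTITY_FIELDS = ("quantity", "relation", "ratio", "units")
_REFERENCE_FIELDS = ("identifiers", "links")
_KNOWN_FIELDS = _NAME_FIELDS + _STRUCTURE_FIELDS + _QUANTITY_FIELDS + _REFERENCE_FIELDS + ("contents",)

#: Structure fields derived from the molfile (recomputed or erased when
#: the molfile changes).
DERIVED_FIELDS = ("formula", "inchi", "inchiKey", "smiles")


@dataclass
class MixComponent:
    """One node of the mixture tree."""

    name: Optional[str] = None
    description: Optional[str] = None
    synonyms: Optional[list] = None
    molfile: Optional[str] = None
    formula: Optional[str] = None
    inchi: Optional[str] = None
    inchiKey: Optional[str] = None
    smiles: Optional[str] = None
    quantity: Optional[Quantity] = None
    identifiers: Optional[dict] = None
    links: Optional[list] = None
    contents: list["MixComponent"] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def walk(self, depth: int = 0, path: tuple = ()) -> Iterator[tuple["MixComponent", int, tuple]]:
        """Pre-order depth-first traversal yielding (node, depth, path)."""
        yield self, depth, path
        for i, child in enumerate(self.contents):
            yield from child.walk(depth + 1, path + (i,))

    @property
    def has_structure(self) -> bool:
        return any(getattr(self, f) is not None for f in ("molfile",) + DERIVED_FIELDS)


@dataclass
class Mixfile:
    """A complete Mixfile document: format version plus the root component."""

    root: MixComponent = field(default_factory=MixComponent)
    version: float = CURRENT_VERSION

    def walk(self) -> Iterator[tuple[MixComponent, int, tuple]]:
        return self.root.walk()


@dataclass(frozen=True)
class Violation:
    """One validation finding. ``severity`` is ``"error"`` (hard) or
    ``"warning"`` (soft); ``path`` locates the node, e.g.
    ``root.contents[1]``."""

    severity: str
    path: str
    message: str


class StructureBackend(Protocol):
    """Pluggable chemistry engine that derives identifiers from a molfile."""

    def from_molfile(self, molfile: str) -> "StructureProps": ...


@dataclass(frozen=True)
class StructureProps:
    formula: Optional[str] = None
    inchi: Optional[str] = None
    inchiKey: Optional[str] = None
    smiles: Optional[str] = None


# ---------------------------------------------------------------------------
# parsing


def _parse_quantity(obj: dict, where: str) -> Optional[Quantity]:
    value = obj.get("quantity")
    relation = obj.get("relation")
    ratio = obj.get("ratio")
    units = obj.get("units")
    if value is None and relation is None and ratio is None and units is None:
        return None
    if isinstance(value, list) and len(value) != 2:
        raise MixfileShapeError(f"{where}: quantity array must have exactly 2 elements")
    if ratio is not None:
        if not isinstance(ratio, list) or len(ratio) != 2:
            raise MixfileShapeError(f"{where}: ratio must be a [numerator, denominator] pair")
    return Quantity(value=value, relation=relation, ratio=ratio, units=units)


def _parse_component(obj: dict, where: str) -> MixComponent:
    if not isinstance(obj, dict):
        raise MixfileShapeError(f"{where}: component must be a JSON object")
    comp = MixComponent(
        name=obj.get("name"),
        description=obj.get("description"),
        synonyms=obj.get("synonyms"),
        molfile=obj.get("molfile"),
        formula=obj.get("formula"),
        inchi=obj.get("inchi"),
        inchiKey=obj.get("inchiKey"),
        smiles=obj.get("smiles"),
        quantity=_parse_quantity(obj, where),
        identifiers=obj.get("identifiers"),
        links=obj.get("links"),
    )
    contents = obj.get("contents")
    if contents is not None:
        if not isinstance(contents, list):
            raise MixfileShapeError(f"{where}: contents must be a list")
        comp.contents = [
            _parse_component(c, f"{where}.contents[{i}]") for i, c in enumerate(contents)
        ]
    comp.extras = {k: v for k, v in obj.items() if k not in _KNOWN_FIELDS and k != "mixfileVersion"}
    return comp


def parse_mixfile(document: str) -> Mixfile:
    """Parse Mixfile JSON text into a :class:`Mixfile` tree.

    Only shape is checked here (quantity arrays of length 2, contents a
    list); semantic checks are :func:`validate`'s job. Unrecognized keys
    land in each node's ``extras`` map.
    """
    try:
        obj = json.loads(document)
    except json.JSONDecodeError as exc:
        raise MixfileParseError(f"not well-formed JSON: {exc}") from exc
    if not isinstance(obj, dict):
        raise MixfileShapeError("top level must be a JSON object")
    version = obj.get("mixfileVersion", CURRENT_VERSION)
    if not isinstance(version, (int, float)):
        raise MixfileShapeError("mixfileVersion must be a number")
    return Mixfile(root=_parse_component(obj, "root"), version=float(version))


# ---------------------------------------------------------------------------
# serialization


def _component_to_obj(comp: MixComponent) -> dict:
    out: dict[str, Any] = {}
    for key in _NAME_FIELDS + _STRUCTURE_FIELDS:
        val = getattr(comp, key)
        if val is not None:
            out[key] = val
    q = comp.quantity
    if q is not None:
        if q.value is not None:
            out["quantity"] = q.value
        if q.relation is not None:
            out["relation"] = q.relation
        if q.ratio is not None:
            out["ratio"] = q.ratio
        if q.units is not None:
            out["units"] = q.units
    for key in _REFERENCE_FIELDS:
        val = getattr(comp, key)
        if val is not None:
            out[key] = val
    out.update(comp.extras)
    if comp.contents:
        out["contents"] = [_component_to_obj(c) for c in comp.contents]
    return out


def serialize_mixfile(mix: Mixfile) -> str:
    """Emit canonical Mixfile JSON (fixed key order, 2-space indent,
    shortest round-trip float formatting).

    Refuses to serialize a document with hard validation violations.
    parse ∘ serialize is the identity on the data model, and serializing
    twice yields byte-identical text.
    """
    hard = [v for v in validate(mix) if v.severity == "error"]
    if hard:
        raise MixfileValidationError(hard)
    obj = {"mixfileVersion": mix.version}
    obj.update(_component_to_obj(mix.root))
    return json.dumps(obj, indent=2, ensure_ascii=False) + "\n"


# ---------------------------------------------------------------------------
# validation


def _is_number(x: Any) -> bool:
    return isinstance(x, (int, float)) and not isinstance(x, bool)


def _validate_quantity(q: Quantity, path: str, out: list[Violation]) -> None:
    from .units import UNIT_NAMES  # local import: units has no model dependency

    err = lambda msg: out.append(Violation("error", path, msg))
    if q.value is not None and q.ratio is not None:
        err("ratio and value are mutually exclusive on one component")
    if q.is_range:
        low, high = q.value
        if not (_is_number(low) and _is_number(high)):
            err("quantity range must contain two numbers")
        elif low > high:
            err(f"range reversed: [{low}, {high}]")
    elif q.value is not None and not _is_number(q.value):
        err("quantity must be a number or a [low, high] pair")
    if q.ratio is not None:
        num, den = q.ratio
        if not (_is_number(num) and _is_number(den)):
            err("ratio must contain two numbers")
        elif den <= 0:
            err(f"ratio denominator must be > 0, got {den}")
    if q.relation is not None and q.relation not in RELATIONS:
        err(f"unknown relation {q.relation!r}")
    if q.value is not None:
        if q.units is None:
            err("units are required when a quantity value is present")
        elif q.units not in UNIT_NAMES:
            err(f"unknown unit {q.units!r}")
    elif q.units is not None and q.ratio is not None:
        out.append(Violation("warning", path, "units are ignored for a pure ratio"))
    elif q.units is not None:
        out.append(Violation("warning", path, "units given without a quantity value"))


def validate(mix: Mixfile) -> list[Violation]:
    """Check every type invariant; returns findings instead of raising.

    Hard errors (severity ``"error"``) make a document unserializable:
    reversed ranges, unknown units or relations, non-positive ratio
    denominators, ratio+value conflicts. Soft warnings flag suspicious but
    legal content, e.g. a non-root node with no name, no structure and no
    children.
    """
    out: list[Violation] = []
    for node, depth, path in mix.walk():
        pstr = "root" + "".join(f".contents[{i}]" for i in path)
        if node.quantity is not None:
            _validate_quantity(node.quantity, pstr, out)
        if depth > 0 and node.name is None and not node.has_structure and not node.contents:
            out.append(Violation("warning", pstr, "component has no name, no structure and no children"))
    return out


# ---------------------------------------------------------------------------
# derived-field normalization


def normalize_derived_fields(
    mix: Mixfile,
    backend: Optional[StructureBackend] = None,
    on_error: Optional[Callable[[str, Exception], None]] = None,
) -> Mixfile:
    """Return a copy in which formula/inchi/inchiKey/smiles are consistent
    with each node's molfile.

    These four fields are transient properties of the molfile: with a
    ``backend`` they are recomputed from it; without one, any that are
    present alongside a molfile are erased (they can no longer be trusted).
    Nodes that carry identifier fields but *no* molfile keep them — that is
    the supported way to describe a structure for which no connection
    table exists.

    A backend failure on a node erases that node's derived fields and is
    reported through ``on_error(path, exception)`` if given.
    """
    mix = copy.deepcopy(mix)
    for node, _depth, path in mix.walk():
        if node.molfile is None:
            continue
        if backend is None:
            for f in DERIVED_FIELDS:
                setattr(node, f, None)
            continue
        try:
            props = backend.from_molfile(node.molfile)
        except Exception as exc:  # backend contract: any failure → erase
            for f in DERIVED_FIELDS:
                setattr(node, f, None)
            if on_error is not None:
                pstr = "root" + "".join(f".contents[{i}]" for i in path)
                on_error(pstr, exc)
            continue
        for f in DERIVED_FIELDS:
            setattr(node, f, getattr(props, f))
    return mix


def flatten(mix: Mixfile) -> list[tuple[MixComponent, int, tuple]]:
    """Pre-order depth-first enumeration of the tree as
    ``(component, depth, path-of-child-indices)``; the root has depth 0
    and an empty path."""
    return list(mix.walk())
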