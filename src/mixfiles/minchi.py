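"""MInChI notation: assembling mixture InChI strings from Mixfile trees
and splitting them back into layers.

A MInChI string has the shape::

    MInChI=0.00.1S/<components>/n<indexing>/g<concentration>

where *components* is the sorted, deduplicated set of prefix-stripped
InChI identifiers joined by ``&``; the *indexing* layer mirrors the
mixture hierarchy with curly braces, giving each structure-bearing node
its 1-based index into the component list; and the *concentration* layer
has the identical brace skeleton with one mnemonic token per node
(value × scale + two-letter unit code, ranges as ``low:high``, ratios as
numerator + ``vp``, blank for unspecified concentrations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .errors import IncompleteMixtureError, MInChIFormatError
from .model import Mixfile, MixComponent, Quantity
from .units import strip_inchi_prefix, to_minchi_concentration

HEADER = "0.00.1S"
PREFIX = "MInChI=" + HEADER + "/"


@dataclass
class MInChIString:
    """A MInChI split into its parts."""

    header: str
    components: list[str]
    indexing: str
    concentration: str


def format_number(value: float) -> str:
    """Render a concentration number compactly: shortest round-trip
    decimal, with ``e±N`` exponent notation only for magnitudes ≥ 1e6 or
    < 1e-3 (0 is plain)."""
    if value != value or math.isinf(value):
        raise ValueError(f"non-finite concentration value {value!r}")
    if value == 0:
        return "0"
    if isinstance(value, int):
        value = float(value)
    mag = abs(value)
    if mag >= 1e6 or mag < 1e-3:
        mantissa, exp = f"{value:e}".split("e")
        mantissa = mantissa.rstrip("0").rstrip(".")
        return f"{mantissa}e{int(exp)}"
    text = repr(value)
    if text.endswith(".0"):
        text = text[:-2]
    if "e" in text:  # repr may pick exponent form just outside our band
        mantissa, exp = text.split("e")
        mantissa = mantissa.rstrip("0").rstrip(".")
        return f"{mantissa}e{int(exp)}"
    return text


def format_concentration(q: Optional[Quantity]) -> str:
    """Render one concentration token.

    An absent or empty quantity yields the empty token (the component is
    the implied remainder). A relation other than ``=`` is prefixed
    verbatim; ranges separate the two scaled values with ``:``.
    """
    if q is None or q.is_empty:
        return ""
    value, code = to_minchi_concentration(q)
    if isinstance(value, list):
        body = f"{format_number(value[0])}:{format_number(value[1])}"
    else:
        body = format_number(value)
    rel = q.relation if q.relation not in (None, "=") else ""
    return f"{rel}{body}{code}"


def collect_component_inchis(mix: Mixfile) -> list[str]:
    """Gather every node's InChI (prefix-stripped) into a sorted,
    deduplicated list — the MInChI component layer.

    A node carrying a molfile but no InChI makes the mixture unassemblable
    and raises :class:`IncompleteMixtureError` with the offending paths;
    run :func:`mixfiles.model.normalize_derived_fields` with a structure
    backend first.
    """
    fragments: set[str] = set()
    missing: list[tuple] = []
    for node, _depth, path in mix.walk():
        if node.inchi:
            fragments.add(strip_inchi_prefix(node.inchi))
        elif node.molfile:
            missing.append(path)
    if missing:
        raise IncompleteMixtureError(missing)
    return sorted(fragments)


def _walk_layers(node: MixComponent, components: list[str]) -> tuple[str, str]:
    child_pairs = [_walk_layers(c, components) for c in node.contents]
    idx = conc = ""
    if child_pairs:
        # canonical sibling order: sort subtree blocks by their indexing text
        order = sorted(range(len(child_pairs)), key=lambda i: child_pairs[i][0])
        idx += "{" + "&".join(child_pairs[i][0] for i in order) + "}"
        conc += "{" + "&".join(child_pairs[i][1] for i in order) + "}"
    if node.inchi:
        idx += str(components.index(strip_inchi_prefix(node.inchi)) + 1)
    conc += format_concentration(node.quantity)
    return idx, conc


def build_layers(mix: Mixfile, components: list[str]) -> tuple[str, str]:
    """Build the indexing and concentration layers in a single recursive
    traversal.

    At each node, the children's blocks are emitted first (wrapped in
    curly braces, joined by ``&``), then the node's own index (empty for a
    structureless node) and concentration token. Both layers therefore
    share an identical brace skeleton. A childless root emits no braces
    at all.
    """
    return _walk_layers(mix.root, components)


def assemble_minchi(mix: Mixfile) -> str:
    """Assemble the full MInChI string for a mixture."""
    components = collect_component_inchis(mix)
    indexing, concentration = build_layers(mix, components)
    return PREFIX + "&".join(components) + "/n" + indexing + "/g" + concentration


def _check_braces(layer: str, what: str) -> None:
    depth = 0
    for ch in layer:
        if ch == "{":
            depth += 1
        elif ch == "}":
            depth -= 1
            if depth < 0:
                raise MInChIFormatError(f"unbalanced braces in {what} layer: {layer!r}")
    if depth != 0:
        raise MInChIFormatError(f"unbalanced braces in {what} layer: {layer!r}")


def _skeleton(layer: str) -> str:
    return "".join(ch for ch in layer if ch in "{}&")


def split_minchi(text: str) -> MInChIString:
    """Split a MInChI string into header, component list, indexing and
    concentration layers.

    The ``/n`` and ``/g`` markers are located from the right: neither
    the indexing nor the concentration layer may contain ``/``, and no
    standard InChI layer uses those letters, so the rightmost occurrences
    are unambiguous.
    """
    if not text.startswith(PREFIX):
        raise MInChIFormatError(f"not a MInChI string (expected {PREFIX!r} prefix)")
    body = text[len(PREFIX):]
    ig = body.rfind("/g")
    if ig < 0:
        raise MInChIFormatError("missing /g concentration marker")
    inx = body.rfind("/n", 0, ig)
    if inx < 0:
        raise MInChIFormatError("missing /n indexing marker")
    comp_text = body[:inx]
    indexing = body[inx + 2:ig]
    concentration = body[ig + 2:]
    _check_braces(indexing, "indexing")
    _check_braces(concentration, "concentration")
    if _skeleton(indexing) != _skeleton(concentration):
        raise MInChIFormatError("indexing and concentration brace skeletons differ")
    components = comp_text.split("&") if comp_text else []
    return MInChIString(HEADER, components, indexing, concentration)
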